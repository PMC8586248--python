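"""Regenerate the shipped default kinetic parameters.

Fits k_p450, k_cdh_carvone, k_cdh_dihydrocarveol and k_endo_carvone to
the four measured endpoints (single-strain carvone titers of MpaLc and
MpaHc; whole-cell activity-assay product endpoints of Mpa and Hc), with
k_endo_carveol held fixed — four observations cannot identify a fifth
coefficient, and the carveol -> dihydrocarvone endogenous path is a
minor flux.  Prints the fitted values to paste into
``pathway_balance.DEFAULT_KINETIC_PARAMS``.

Run from the repository root:  python scripts/calibrate_defaults.py
"""

from qconpath.pathway_balance import (
    CalibrationObservation,
    KineticParams,
    calibrate_rate_constants,
    simulate_bioconversion,
    whole_cell_activity,
)
from qconpath.synthetic_data import make_scenario

FREE = ("k_p450", "k_cdh_carvone", "k_cdh_dihydrocarveol", "k_endo_carvone")

START = KineticParams(
    k_p450=2.3e-06,
    k_cdh_carvone=5.0e-05,
    k_cdh_dihydrocarveol=5.0e-06,
    k_endo_carveol=2.0e-04,
    k_endo_carvone=3.9e-04,
)


def observations():
    mpalc = make_scenario("MpaLc")
    mpahc = make_scenario("MpaHc")
    mpa = make_scenario("Mpa")
    hc = make_scenario("Hc")
    return [
        CalibrationObservation(mpalc.pooled(), mpalc.conditions, {"carvone": 44.0}),
        CalibrationObservation(mpahc.pooled(), mpahc.conditions, {"carvone": 2.9}),
        # activity endpoints: activity * duration * OD
        CalibrationObservation(
            mpa.pooled(), mpa.conditions, {"trans_carveol": 2.4 * 16.0 * 20.0}
        ),
        CalibrationObservation(
            hc.pooled(), hc.conditions, {"carvone": 4.9 * 16.0 * 20.0}
        ),
    ]


def main() -> None:
    params, residuals = calibrate_rate_constants(
        observations(), free=FREE, start=START
    )
    print("fitted parameters:")
    for name in (
        "k_p450", "k_cdh_carvone", "k_cdh_dihydrocarveol",
        "k_endo_carveol", "k_endo_carvone",
    ):
        print(f"    {name}={getattr(params, name):.6g},")
    print("relative residuals:", residuals)
    for scenario_name in ("MpaLc", "MpaHc", "Mpa", "Hc"):
        sc = make_scenario(scenario_name)
        tc = simulate_bioconversion(sc.pooled(), sc.conditions, params)
        print(
            f"{scenario_name}: carvone {tc.final('carvone'):.2f} mg/L, "
            f"carveol {tc.final('trans_carveol'):.2f} mg/L, "
            f"activity({sc.product}) "
            f"{whole_cell_activity(tc, sc.product, sc.conditions):.3f}"
        )


if __name__ == "__main__":
    main()
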