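"""Whole-cell limonene -> carvone bioconversion model and enzyme balancing.

The pathway and its by-product branches:

    limonene --(P450/CPR)--> trans-carveol --(CDH)--> carvone
    trans-carveol --(CDH branch)-->            dihydrocarveol
    trans-carveol --(endogenous reductase)-->  dihydrocarvone
    carvone       --(endogenous reductase)-->  dihydrocarvone

Kinetics are mass-action, first order in substrate, with each rate
proportional to the catalysing enzyme's copies-per-cell times the cell
density (OD600):

    rate = k * E * OD * [substrate],   E in copies/cell

The hydroxylation step requires electron transfer from CPR, so its
effective enzyme level is min(P450, CPR); CPR is normally in large
excess so this rarely binds.  Substrate volatilization and phase
partitioning are ignored (reactions are run ice-cooled in sealed vials).

Rate coefficients carry units of (copies/cell)^-1 OD^-1 h^-1.  The
shipped defaults were obtained by least-squares calibration of the model
against four measured endpoints (two single-strain carvone titers and
the two whole-cell activity assays); ``scripts/calibrate_defaults.py``
regenerates them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

SPECIES = (
    "limonene",
    "trans_carveol",
    "carvone",
    "dihydrocarveol",
    "dihydrocarvone",
)

#: g/mol; standard chemistry values
MOLAR_MASS_G_PER_MOL = {
    "limonene": 136.23,
    "trans_carveol": 152.23,
    "carvone": 150.22,
    "dihydrocarveol": 154.25,
    "dihydrocarvone": 152.23,
}


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class EnzymeProfile:
    """Per-cell enzyme levels of one strain (copies/cell; endogenous
    reductase on a dimensionless unit scale, 1.0 = wild-type)."""

    name: str = ""
    p450: float = 0.0
    cpr: float = 0.0
    cdh: float = 0.0
    endogenous: float = 1.0

    def __post_init__(self) -> None:
        if min(self.p450, self.cpr, self.cdh, self.endogenous) < 0:
            raise KineticsError("enzyme levels must be non-negative")

    def p450_cdh_ratio(self) -> float:
        return self.p450 / self.cdh if self.cdh > 0 else math.inf


@dataclass(frozen=True)
class ReactionConditions:
    od600: float = 20.0
    duration_h: float = 16.0
    temperature_c: float = 14.0  # informational
    initial_mg_per_l: dict[str, float] = field(
        default_factory=lambda: {"limonene": 100.0}
    )

    def __post_init__(self) -> None:
        if self.od600 <= 0 or self.duration_h <= 0:
            raise KineticsError("od600 and duration must be positive")
        unknown = set(self.initial_mg_per_l) - set(SPECIES)
        if unknown:
            raise KineticsError(f"unknown species: {sorted(unknown)}")


@dataclass(frozen=True)
class KineticParams:
    """Second-order rate coefficients, (copies/cell)^-1 OD^-1 h^-1."""

    k_p450: float  # limonene -> trans-carveol (min(P450, CPR))
    k_cdh_carvone: float  # trans-carveol -> carvone (CDH)
    k_cdh_dihydrocarveol: float  # trans-carveol -> dihydrocarveol (CDH branch)
    k_endo_carveol: float  # trans-carveol -> dihydrocarvone (endogenous)
    k_endo_carvone: float  # carvone -> dihydrocarvone (endogenous)

    def __post_init__(self) -> None:
        if min(self.as_array()) < 0:
            raise KineticsError("rate coefficients must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.k_p450,
                self.k_cdh_carvone,
                self.k_cdh_dihydrocarveol,
                self.k_endo_carveol,
                self.k_endo_carvone,
            ]
        )


PARAM_NAMES = (
    "k_p450",
    "k_cdh_carvone",
    "k_cdh_dihydrocarveol",
    "k_endo_carveol",
    "k_endo_carvone",
)

#: calibrated against the four measured endpoints; see module docstring
DEFAULT_KINETIC_PARAMS = KineticParams(
    k_p450=2.44588e-06,
    k_cdh_carvone=9.53731e-05,
    k_cdh_dihydrocarveol=8.17544e-06,
    k_endo_carveol=2.0e-04,
    k_endo_carvone=4.62701e-04,
)


@dataclass
class Timecourse:
    """Species concentrations (mg/L) over the reaction time grid (h)."""

    times: np.ndarray
    concentrations: dict[str, np.ndarray]

    def final(self, species: str) -> float:
        return float(self.concentrations[species][-1])

    def molar(self, species: str) -> np.ndarray:
        """Concentration in mmol/L."""
        return self.concentrations[species] / MOLAR_MASS_G_PER_MOL[species]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, **self.concentrations})


def _rates(
    c: tuple[float, ...], e1: float, e2: float, e3: float, k: np.ndarray
) -> tuple[float, ...]:
    lim, cv, cn, _, _ = c
    r1 = k[0] * e1 * lim
    r2 = k[1] * e2 * cv
    r3 = k[2] * e2 * cv
    r4 = k[3] * e3 * cv
    r5 = k[4] * e3 * cn
    return (-r1, r1 - r2 - r3 - r4, r2 - r5, r3, r4 + r5)


def simulate_bioconversion(
    profile: EnzymeProfile,
    conditions: ReactionConditions | None = None,
    params: KineticParams | None = None,
    step_h: float = 0.01,
) -> Timecourse:
    """Integrate the pathway ODEs with fixed-step classical Runge-Kutta.

    Internally in mmol/L (1:1 molar stoichiometry makes total moles a
    conserved quantity); reported in mg/L.  Step size is at most 0.01 h.
    """
    conditions = conditions or ReactionConditions()
    params = params or DEFAULT_KINETIC_PARAMS
    if step_h <= 0:
        raise KineticsError("step_h must be positive")
    step_h = min(step_h, 0.01)
    od = conditions.od600
    e1 = min(profile.p450, profile.cpr) * od
    e2 = profile.cdh * od
    e3 = profile.endogenous * od
    k = params.as_array()

    n_steps = int(math.ceil(conditions.duration_h / step_h))
    dt = conditions.duration_h / n_steps
    c = tuple(
        conditions.initial_mg_per_l.get(s, 0.0) / MOLAR_MASS_G_PER_MOL[s]
        for s in SPECIES
    )
    trajectory = np.empty((n_steps + 1, len(SPECIES)))
    trajectory[0] = c
    for i in range(n_steps):
        k1 = _rates(c, e1, e2, e3, k)
        k2 = _rates(tuple(ci + 0.5 * dt * d for ci, d in zip(c, k1)), e1, e2, e3, k)
        k3 = _rates(tuple(ci + 0.5 * dt * d for ci, d in zip(c, k2)), e1, e2, e3, k)
        k4 = _rates(tuple(ci + dt * d for ci, d in zip(c, k3)), e1, e2, e3, k)
        c = tuple(
            ci + dt / 6.0 * (a + 2 * b + 2 * cc + d)
            for ci, a, b, cc, d in zip(c, k1, k2, k3, k4)
        )
        trajectory[i + 1] = c
    times = np.linspace(0.0, conditions.duration_h, n_steps + 1)
    concentrations = {
        s: trajectory[:, j] * MOLAR_MASS_G_PER_MOL[s] for j, s in enumerate(SPECIES)
    }
    return Timecourse(times=times, concentrations=concentrations)


def whole_cell_activity(
    timecourse: Timecourse, product: str, conditions: ReactionConditions
) -> float:
    """Final product concentration per hour per OD600 (mg L-1 h-1 OD-1)."""
    if product not in timecourse.concentrations:
        raise KineticsError(f"{product!r} not in timecourse")
    return timecourse.final(product) / (conditions.duration_h * conditions.od600)


def mixture_ratio(
    profile_a: EnzymeProfile,
    profile_b: EnzymeProfile,
    od_a: float,
    od_b: float,
) -> float:
    """Population P450/CDH ratio of an OD-based two-strain mixture.

    Cells per OD are assumed equal across strains.  Returns ``inf`` when
    the mixture contains no CDH (flag, not an exception).
    """
    if od_a < 0 or od_b < 0 or od_a + od_b == 0:
        raise KineticsError("OD contributions must be non-negative, not both zero")
    p450 = profile_a.p450 * od_a + profile_b.p450 * od_b
    cdh = profile_a.cdh * od_a + profile_b.cdh * od_b
    return p450 / cdh if cdh > 0 else math.inf


def pooled_profile(
    profiles: dict[str, EnzymeProfile], od_weights: dict[str, float], name: str = "mix"
) -> EnzymeProfile:
    """OD-weighted per-cell average profile of a strain mixture."""
    total = sum(od_weights.values())
    if total <= 0:
        raise KineticsError("total OD weight must be positive")

    def avg(attr: str) -> float:
        return sum(getattr(profiles[s], attr) * w for s, w in od_weights.items()) / total

    return EnzymeProfile(
        name=name, p450=avg("p450"), cpr=avg("cpr"), cdh=avg("cdh"),
        endogenous=avg("endogenous"),
    )


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationObservation:
    """One measured experiment: conditions plus observed final concentrations."""

    profile: EnzymeProfile
    conditions: ReactionConditions
    endpoints: dict[str, float]  # species -> mg/L at end of reaction


class CalibrationError(RuntimeError):
    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


def calibrate_rate_constants(
    observations: list[CalibrationObservation],
    free: tuple[str, ...] = PARAM_NAMES,
    start: KineticParams | None = None,
    step_h: float = 0.01,
) -> tuple[KineticParams, np.ndarray]:
    """Fit rate coefficients to observed endpoints by least squares.

    Minimises relative endpoint errors over ``free`` parameters in log
    space (coefficients are positive and span decades); the remaining
    parameters stay at their ``start`` values.  Deterministic given a
    fixed starting point.  Raises :class:`CalibrationError` carrying the
    residual vector when the optimizer fails to converge.
    """
    n_obs = sum(len(o.endpoints) for o in observations)
    if n_obs < len(free):
        raise CalibrationError(
            f"{n_obs} observations cannot constrain {len(free)} free parameters"
        )
    start = start or DEFAULT_KINETIC_PARAMS
    unknown = set(free) - set(PARAM_NAMES)
    if unknown:
        raise CalibrationError(f"unknown parameters: {sorted(unknown)}")

    def to_params(x: np.ndarray) -> KineticParams:
        values = {name: getattr(start, name) for name in PARAM_NAMES}
        for name, xi in zip(free, x):
            values[name] = 10.0 ** xi
        return KineticParams(**values)

    def residuals(x: np.ndarray) -> np.ndarray:
        params = to_params(x)
        res = []
        for obs in observations:
            tc = simulate_bioconversion(obs.profile, obs.conditions, params, step_h)
            for species, target in obs.endpoints.items():
                res.append((tc.final(species) - target) / target)
        return np.array(res)

    x0 = np.array([math.log10(max(getattr(start, name), 1e-12)) for name in free])
    fit = least_squares(residuals, x0, method="lm")
    final_res = residuals(fit.x)
    if not fit.success:
        raise CalibrationError(
            f"calibration did not converge: {fit.message}", residuals=final_res
        )
    return to_params(fit.x), final_res


# ---------------------------------------------------------------------------
# optimum analysis


@dataclass
class OptimumResult:
    ratio: float
    titer_mg_per_l: float
    table: pd.DataFrame


def optimum_ratio_analysis(points: list[tuple[float, float]]) -> OptimumResult:
    """Pick the P450/CDH ratio maximising carvone titer.

    Ties break toward the larger ratio: excess CDH is the documented
    harm, so among equal titers the CDH-leaner condition is preferred.
    Also returns the ratio-vs-titer table for plotting.
    """
    if not points:
        raise KineticsError("need at least one (ratio, titer) point")
    best_ratio, best_titer = max(points, key=lambda rt: (rt[1], rt[0]))
    table = pd.DataFrame(points, columns=["p450_cdh_ratio", "carvone_mg_per_l"])
    table = table.sort_values("p450_cdh_ratio").reset_index(drop=True)
    return OptimumResult(ratio=best_ratio, titer_mg_per_l=best_titer, table=table)
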