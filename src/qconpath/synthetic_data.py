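"""Synthetic data generators with known ground truth.

Everything the pipeline consumes can be generated here: a fixture
proteome and concatamer standard, MRM peak tables with a labeling-deficit
model (99% 13C enrichment), measurement noise and negative-control
background, sample metadata, calibration series, digestion time courses,
and bioconversion titer tables — all from named strain scenarios.

The scenarios encode the study conditions: single strains expressing
P450/CPR (Mpa), CDH (Hc), both from high-copy plasmids (MpaHc) or with
CDH on a low-copy plasmid (MpaLc), OD-based Mpa:Hc mixtures, and a
wild-type negative control.  Each scenario's per-cell P450/CDH ground
truth equals the measured ratio for that condition (0.004, 12, 0.388,
3.4, 16).  Because those mixture ratios are not mutually consistent
with proportional OD mixing of a single strain pair, each mixture
carries its own independent ground-truth profiles; absolute copy-number
magnitudes are synthetic choices (see docs/methods.md).

Heavy/light MRM areas follow the generative model inverted by the
quantification pipeline:

    heavy = gain * spiked_pmol * p**nC * release_efficiency
    light = gain * true_pmol + background      (then lognormal noise)

where ``p**nC`` is the fully labeled fraction of the standard (only the
heavy monoisotopic peak is integrated) and ``release_efficiency`` < 1
models incomplete tryptic release of a peptide from a problematic
concatamer junction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .isotopes import elemental_composition, fully_labeled_fraction
from .mrm_quant import AVOGADRO
from .pathway_balance import (
    DEFAULT_KINETIC_PARAMS,
    EnzymeProfile,
    KineticParams,
    ReactionConditions,
    mixture_ratio,
    pooled_profile,
    simulate_bioconversion,
)
from .qconcat_design import ConcatamerDesign, build_concatamer, protein_mass
from .seqdigest import PeptideSpec, ProteinRecord, digest

# ---------------------------------------------------------------------------
# fixture peptides and proteome (synthetic stand-ins: the real target and
# standard sequences are not redistributable, so placeholder peptides and
# framework sequences are generated here; the three literature-reported
# peptides are embedded in realistic tryptic context)

PEPTIDE_CYP71D18_1 = "VLDPNFADR"
PEPTIDE_CYP71D18_2 = "AGDFLSTVNER"  # synthetic placeholder
PEPTIDE_ATR2_1 = "TLSEGQAVFDK"  # synthetic placeholder
PEPTIDE_ATR2_2 = "VVDDILVEQGAQR"
PEPTIDE_CYP102A1_1 = "EDTVLGGEYPLEK"
PEPTIDE_ISPD_1 = "VGSDLATFQEK"  # synthetic placeholder
PEPTIDE_ISPD_2 = "ALSDGTVFNQR"  # synthetic placeholder

#: quantification peptides per target protein (two each)
QUANT_PEPTIDES: dict[str, tuple[str, str]] = {
    "CYP71D18": (PEPTIDE_CYP71D18_1, PEPTIDE_CYP71D18_2),
    "ATR2": (PEPTIDE_ATR2_1, PEPTIDE_ATR2_2),
    "ISPD": (PEPTIDE_ISPD_1, PEPTIDE_ISPD_2),
}

PROTEIN_ROLES = {
    "CYP71D18": "P450",
    "ATR2": "CPR",
    "ISPD": "CDH",
    "CYP102A1": "P450",
    "LimC": "CDH",
}

PEPTIDE_TO_PROTEIN = {
    pep: prot for prot, peps in QUANT_PEPTIDES.items() for pep in peps
}

#: concatamer order; the reported miscleavage junction (R|E) is the
#: VVDDILVEQGAQR -> EDTVLGGEYPLEK boundary
CONCATAMER_ORDER = (
    PEPTIDE_CYP71D18_1,
    PEPTIDE_CYP71D18_2,
    PEPTIDE_ATR2_1,
    PEPTIDE_ATR2_2,
    PEPTIDE_CYP102A1_1,
    PEPTIDE_ISPD_1,
    PEPTIDE_ISPD_2,
)

HIS_LEADER = "MGSSHHHHHHSSGLVPR"  # pET-28a style His-tag leader
_FILLER_UNIT = "GSSTAK"  # inert tryptic filler for mass padding
_TARGET_AVERAGE_MASS_DA = 19.82e3  # implied by 2 ug == 100.9 pmol

_SPACERS = ("ASLTEGSQVF", "GTELSAQVSF", "SEVGALTQSF")


def _embed(peptides: tuple[str, ...], prefix: str) -> str:
    """Frame peptides with K-terminated spacers so they digest out cleanly."""
    parts = ["M", prefix, "K"]
    for i, pep in enumerate(peptides):
        parts.append(pep)
        parts.append(_SPACERS[i % len(_SPACERS)])
        parts.append("K")
    parts.append("AGSLTE")
    return "".join(parts)


def fixture_proteome() -> list[ProteinRecord]:
    """Deterministic five-protein fixture proteome (synthetic framework
    sequences embedding the quantification peptides)."""
    sequences = {
        "CYP71D18": _embed(QUANT_PEPTIDES["CYP71D18"], "GAFESLTQ"),
        "ATR2": _embed(QUANT_PEPTIDES["ATR2"], "SLETGAQF"),
        "ISPD": _embed(QUANT_PEPTIDES["ISPD"], "TQGASLEF"),
        "CYP102A1": _embed((PEPTIDE_CYP102A1_1,), "QESLGATF"),
        "LimC": _embed((), "GELTASQF"),
    }
    return [
        ProteinRecord(id=name, sequence=seq, role=PROTEIN_ROLES[name])
        for name, seq in sequences.items()
    ]


def write_fixture_fasta(path) -> None:
    lines = []
    for rec in fixture_proteome():
        lines.append(f">{rec.id} role={rec.role}")
        lines.append(rec.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


def fixture_concatamer() -> ConcatamerDesign:
    """Fixture QconCAT standard (synthetic): the seven designed peptides
    behind a His-tag leader, padded with inert tryptic filler so its
    average mass matches the 19.82 kDa implied by 2 ug == 100.9 pmol."""
    proteome = {p.id: p for p in fixture_proteome()}
    specs: list[PeptideSpec] = []
    for pep in CONCATAMER_ORDER:
        parent = PEPTIDE_TO_PROTEIN.get(pep, "CYP102A1")
        for candidate in digest(proteome[parent], max_missed=0):
            if candidate.sequence == pep:
                specs.append(candidate)
                break
        else:  # pragma: no cover - fixture invariant
            raise AssertionError(f"{pep} not released from fixture {parent}")
    core = HIS_LEADER + "".join(CONCATAMER_ORDER)
    unit_mass = protein_mass(_FILLER_UNIT, "average") - protein_mass("", "average")
    deficit = _TARGET_AVERAGE_MASS_DA - protein_mass(core, "average")
    n_units = max(0, round(deficit / unit_mass))
    return build_concatamer(
        specs,
        leader_tag=HIS_LEADER,
        trailer_tag=_FILLER_UNIT * n_units,
        name="qconcat1_fixture",
    )


# ---------------------------------------------------------------------------
# strain scenarios

SCENARIO_NAMES = (
    "Mpa",
    "Hc",
    "MpaHc",
    "MpaLc",
    "mix_100_100",
    "mix_100_10",
    "mix_100_1",
    "negative_control",
)


@dataclass(frozen=True)
class StrainScenario:
    """Named study condition with ground-truth enzyme profiles.

    ``profiles`` holds one entry for single strains, two for mixtures
    (keyed by strain); ``od_weights`` gives the OD-based mixing ratio.
    ``truth_ratio`` is the condition's ground-truth P450/CDH ratio (None
    when undefined, e.g. no CDH present).
    """

    name: str
    profiles: dict[str, EnzymeProfile]
    conditions: ReactionConditions
    od_weights: dict[str, float] | None = None
    product: str = "carvone"
    truth_ratio: float | None = None

    def population_ratio(self) -> float:
        if self.od_weights is not None:
            (a, b) = sorted(self.od_weights)
            return mixture_ratio(
                self.profiles[a], self.profiles[b],
                self.od_weights[a], self.od_weights[b],
            )
        (profile,) = self.profiles.values()
        return profile.p450_cdh_ratio()

    def pooled(self) -> EnzymeProfile:
        if self.od_weights is None:
            (profile,) = self.profiles.values()
            return profile
        return pooled_profile(self.profiles, self.od_weights, name=self.name)


def _bioconversion(limonene: float = 100.0) -> ReactionConditions:
    return ReactionConditions(initial_mg_per_l={"limonene": limonene})


def make_scenario(name: str) -> StrainScenario:
    """Ground-truth scenario by name; see module docstring for the design."""
    mpa = EnzymeProfile(name="Mpa", p450=1600.0, cpr=16000.0, cdh=0.0)
    hc = EnzymeProfile(name="Hc", p450=0.0, cpr=0.0, cdh=1.0e4)
    scenarios = {
        "Mpa": StrainScenario(
            name="Mpa",
            profiles={"Mpa": mpa},
            conditions=ReactionConditions(initial_mg_per_l={"limonene": 1000.0}),
            product="trans_carveol",
        ),
        "Hc": StrainScenario(
            name="Hc",
            profiles={"Hc": hc},
            conditions=ReactionConditions(initial_mg_per_l={"trans_carveol": 2000.0}),
            product="carvone",
        ),
        "MpaHc": StrainScenario(
            name="MpaHc",
            profiles={
                "MpaHc": EnzymeProfile(
                    name="MpaHc", p450=40.0, cpr=16000.0, cdh=1.0e4
                )
            },
            conditions=_bioconversion(),
            truth_ratio=0.004,
        ),
        "MpaLc": StrainScenario(
            name="MpaLc",
            profiles={
                "MpaLc": EnzymeProfile(
                    name="MpaLc", p450=1200.0, cpr=16000.0, cdh=100.0
                )
            },
            conditions=_bioconversion(),
            truth_ratio=12.0,
        ),
        "mix_100_100": StrainScenario(
            name="mix_100_100",
            profiles={
                "Mpa": EnzymeProfile(name="Mpa", p450=970.0, cpr=9700.0, cdh=0.0),
                "Hc": EnzymeProfile(name="Hc", cdh=2500.0),
            },
            od_weights={"Mpa": 100.0, "Hc": 100.0},
            conditions=_bioconversion(),
            truth_ratio=0.388,
        ),
        "mix_100_10": StrainScenario(
            name="mix_100_10",
            profiles={
                "Mpa": EnzymeProfile(name="Mpa", p450=680.0, cpr=6800.0, cdh=0.0),
                "Hc": EnzymeProfile(name="Hc", cdh=2000.0),
            },
            od_weights={"Mpa": 100.0, "Hc": 10.0},
            conditions=_bioconversion(),
            truth_ratio=3.4,
        ),
        "mix_100_1": StrainScenario(
            name="mix_100_1",
            profiles={"Mpa": mpa, "Hc": hc},
            od_weights={"Mpa": 100.0, "Hc": 1.0},
            conditions=_bioconversion(),
            truth_ratio=16.0,
        ),
        "negative_control": StrainScenario(
            name="negative_control",
            profiles={
                "negative_control": EnzymeProfile(name="negative_control")
            },
            conditions=_bioconversion(),
        ),
    }
    try:
        return scenarios[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {SCENARIO_NAMES}"
        ) from None


# ---------------------------------------------------------------------------
# MRM peak-table synthesis


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for synthetic peak tables.

    ``cv`` is the multiplicative lognormal coefficient of variation;
    ``background_frac`` sets the additive light-channel background as a
    fraction of the median heavy area; ``enrichment`` is the 13C
    probability per carbon of the standard; ``heavy_release`` models
    incomplete standard release at problematic concatamer junctions.
    """

    cv: float = 0.05
    background_frac: float = 0.005
    enrichment: float = 0.99
    heavy_release: dict[str, float] = field(
        default_factory=lambda: {PEPTIDE_ATR2_2: 0.7}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must be in [0, 1]")


NOISE_FREE = NoiseModel(cv=0.0, background_frac=0.0)


@dataclass
class SyntheticPeakDataset:
    peaks: pd.DataFrame
    meta: pd.DataFrame
    truth: dict

    def write(self, outdir, stem: str = "peaks") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.peaks.to_csv(outdir / f"{stem}.csv", index=False)
        self.meta.to_csv(outdir / f"{stem}_meta.csv", index=False)
        (outdir / f"{stem}_truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n"
        )


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def synth_peak_table(
    scenario: StrainScenario,
    noise: NoiseModel = NOISE_FREE,
    replicates: int = 3,
    spiked_pmol: float = 100.9,
    cells_in_digest: float = 4.0e9,
    gain: float = 1.0e4,
) -> SyntheticPeakDataset:
    """MRM peak table + metadata + ground-truth sidecar for a scenario.

    One digest per population per replicate, plus matched negative
    controls carrying standard (heavy) signal and background-only light
    signal.  Seeded and deterministic.
    """
    rng = np.random.default_rng(noise.seed)
    peptides = list(PEPTIDE_TO_PROTEIN)
    corrections = {
        pep: fully_labeled_fraction(elemental_composition(pep), noise.enrichment)
        for pep in peptides
    }
    heavy_clean = {
        pep: gain * spiked_pmol * corrections[pep] * noise.heavy_release.get(pep, 1.0)
        for pep in peptides
    }
    background = noise.background_frac * float(np.median(list(heavy_clean.values())))

    rows, meta_rows = [], []
    truth: dict = {
        "scenario": scenario.name,
        "copies_per_cell": {},
        "truth_ratio": scenario.truth_ratio,
        "enrichment": noise.enrichment,
        "spiked_pmol": spiked_pmol,
        "cells_in_digest": cells_in_digest,
        "background": background,
    }

    def add_sample(sample_id: str, population: str, copies: dict[str, float],
                   is_control: bool) -> None:
        for pep in peptides:
            protein = PEPTIDE_TO_PROTEIN[pep]
            true_pmol = copies.get(protein, 0.0) * cells_in_digest / AVOGADRO * 1e12
            light = (0.0 if is_control else gain * true_pmol) + background
            heavy = heavy_clean[pep]
            light_f, heavy_f = _lognormal_factor(rng, noise.cv, 2)
            rows.append((sample_id, pep, "light", light * light_f))
            rows.append((sample_id, pep, "heavy", heavy * heavy_f))
        meta_rows.append(
            {
                "sample_id": sample_id,
                "spiked_pmol": spiked_pmol,
                "total_protein_ug": 50.0,
                "cells_in_digest": cells_in_digest,
                "is_negative_control": is_control,
                "population": population,
            }
        )

    for population, profile in scenario.profiles.items():
        copies = {"CYP71D18": profile.p450, "ATR2": profile.cpr, "ISPD": profile.cdh}
        truth["copies_per_cell"][population] = copies
        for rep in range(1, replicates + 1):
            add_sample(f"{population}_rep{rep}", population, copies, False)
    for rep in range(1, replicates + 1):
        add_sample(f"control_rep{rep}", "negative_control", {}, True)

    peaks = pd.DataFrame(rows, columns=["sample_id", "peptide", "channel", "area"])
    return SyntheticPeakDataset(peaks=peaks, meta=pd.DataFrame(meta_rows), truth=truth)


def recovered_p450_cdh_ratio(
    scenario: StrainScenario, abundances: pd.DataFrame
) -> float:
    """P450/CDH ratio from pipeline output for a scenario.

    Single strains: per-cell P450/CDH of the one population.  Mixtures:
    OD-weighted population ratio from the per-strain recovered profiles.
    """
    def profile_of(population: str) -> EnzymeProfile:
        sub = abundances[abundances["population"] == population]
        values = dict(zip(sub["protein"], sub["copies_per_cell"]))
        return EnzymeProfile(
            name=population,
            p450=values.get("CYP71D18", 0.0),
            cpr=values.get("ATR2", 0.0),
            cdh=values.get("ISPD", 0.0),
        )

    if scenario.od_weights is not None:
        (a, b) = sorted(scenario.od_weights)
        return mixture_ratio(
            profile_of(a), profile_of(b),
            scenario.od_weights[a], scenario.od_weights[b],
        )
    (population,) = scenario.profiles
    return profile_of(population).p450_cdh_ratio()


# ---------------------------------------------------------------------------
# titer tables, calibration series, digestion time courses


def synth_titer_table(
    scenario: StrainScenario,
    noise: NoiseModel = NOISE_FREE,
    replicates: int = 3,
    params: KineticParams | None = None,
) -> pd.DataFrame:
    """Per-replicate endpoint titer table from the kinetic model.

    Columns: scenario, replicate, species, concentration_mg_per_L, time_h.
    """
    params = params or DEFAULT_KINETIC_PARAMS
    rng = np.random.default_rng(noise.seed)
    tc = simulate_bioconversion(scenario.pooled(), scenario.conditions, params)
    rows = []
    for rep in range(1, replicates + 1):
        for species in tc.concentrations:
            value = tc.final(species) * _lognormal_factor(rng, noise.cv, 1)[0]
            rows.append(
                {
                    "scenario": scenario.name,
                    "replicate": rep,
                    "species": species,
                    "concentration_mg_per_L": value,
                    "time_h": scenario.conditions.duration_h,
                }
            )
    return pd.DataFrame(rows)


def synth_calibration_points(
    slope: float = 1.0 / 100.9,
    amounts_pmol: tuple[float, ...] = (0.25, 1.0, 5.0, 25.0, 100.0, 500.0, 2500.0),
    cv: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """External calibration series: response ratio proportional to amount."""
    rng = np.random.default_rng(seed)
    factors = _lognormal_factor(rng, cv, len(amounts_pmol))
    return [(a, slope * a * f) for a, f in zip(amounts_pmol, factors)]


def synth_digestion_timecourse(
    k_per_h: float = 0.5,
    times_h: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 24.0),
    completeness: float = 1.0,
) -> list[tuple[float, float]]:
    """First-order tryptic release curve: signal = completeness*(1-e^-kt)."""
    return [(t, completeness * (1.0 - math.exp(-k_per_h * t))) for t in times_h]
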