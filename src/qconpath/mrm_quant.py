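"""MRM peak-area tables -> absolute protein abundances (copies per cell).

Quantification follows the light/heavy internal-standard scheme: for each
quantification peptide the light (12C, sample-derived) peak area is
divided by the heavy (13C, QconCAT-derived) peak area, multiplied by the
spiked standard amount, and converted to copies per cell through the
number of cells represented in the digest.  Supporting steps:

* negative-control subtraction of the light channel (background signal),
  clamped at zero;
* optional labeling-deficit correction ``p**nC`` — the heavy
  monoisotopic peak represents only the fully labeled fraction of the
  standard, so the raw ratio overestimates the sample amount by
  ``1/p**nC`` when only that peak is integrated;
* peptide exclusion (e.g. junction-miscleavage victims) and averaging of
  the remaining peptides per protein, with replicate SD taken across
  replicate samples, not across peptides;
* QC: external calibration-curve linearity and digestion time-course
  plateau detection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .isotopes import elemental_composition, fully_labeled_fraction

AVOGADRO = 6.02214076e23

PEAK_COLUMNS = ["sample_id", "peptide", "channel", "area"]
META_COLUMNS = [
    "sample_id", "spiked_pmol", "total_protein_ug",
    "cells_in_digest", "is_negative_control",
]
CHANNELS = ("light", "heavy")


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


class QuantificationError(ValueError):
    """Quantification cannot proceed (e.g. every peptide excluded)."""


@dataclass(frozen=True)
class PeakMeasurement:
    sample_id: str
    peptide: str
    channel: str
    area: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise SchemaError(f"channel must be one of {CHANNELS}")
        if self.area < 0:
            raise SchemaError("area must be non-negative")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    spiked_pmol: float = 100.9
    total_protein_ug: float = 50.0
    cells_in_digest: float = 4.0e9
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if self.spiked_pmol <= 0:
            raise SchemaError("spiked_pmol must be positive")
        if not self.is_negative_control and self.cells_in_digest <= 0:
            raise SchemaError("cells_in_digest must be positive")


@dataclass
class ProteinAbundance:
    """Per-protein result: mean copies/cell over used peptides and replicates."""

    protein_id: str
    copies_per_cell: float
    per_peptide: dict[str, float]
    sd: float = float("nan")
    n_replicates: int = 1
    peptides_used: list[str] = field(default_factory=list)
    peptides_excluded: dict[str, str] = field(default_factory=dict)


@dataclass
class CalibrationCurve:
    peptide: str
    points: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    validated_range: tuple[float, float]


@dataclass
class PlateauResult:
    time_h: float
    plateau_reached: bool


# ---------------------------------------------------------------------------
# readers


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def read_peak_table(path) -> pd.DataFrame:
    """Read and validate an MRM peak table (CSV/TSV).

    Required columns: sample_id, peptide, channel (light|heavy), area.
    Unknown columns are preserved as annotations.
    """
    df = _read_table(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"peak table is missing columns: {missing}")
    bad_channel = set(df["channel"].unique()) - set(CHANNELS)
    if bad_channel:
        raise SchemaError(f"unknown channel values: {sorted(bad_channel)}")
    if (df["area"] < 0).any():
        raise SchemaError("peak areas must be non-negative")
    if df.duplicated(subset=["sample_id", "peptide", "channel"]).any():
        raise SchemaError("duplicated (sample_id, peptide, channel) rows")
    return df


def read_sample_meta(path) -> pd.DataFrame:
    """Read sample metadata from CSV or JSON (list of records)."""
    if str(path).endswith(".json"):
        df = pd.DataFrame(json.loads(Path(path).read_text()))
    else:
        df = _read_table(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample metadata is missing columns: {missing}")
    df["is_negative_control"] = df["is_negative_control"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# core quantification


def subtract_negative_control(
    samples: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """Subtract control light areas (mean per peptide), clamped at zero.

    Heavy areas are untouched; peptides missing from the control are
    passed through with a warning.
    """
    out = samples.copy()
    ctrl_light = (
        control[control["channel"] == "light"].groupby("peptide")["area"].mean()
    )
    missing = set(samples["peptide"].unique()) - set(ctrl_light.index)
    if missing:
        warnings.warn(
            f"no negative-control signal for peptides {sorted(missing)}; "
            "light areas left unsubtracted",
            stacklevel=2,
        )
    is_light = out["channel"] == "light"
    background = out.loc[is_light, "peptide"].map(ctrl_light).fillna(0.0)
    out.loc[is_light, "area"] = (out.loc[is_light, "area"] - background).clip(lower=0.0)
    return out


def quantify_peptide(
    light_area: float,
    heavy_area: float,
    meta: SampleMeta,
    deficit_correction: float | None = None,
) -> float:
    """Peptide amount in pmol from the light/heavy peak-area ratio.

    ``deficit_correction`` is the fully labeled fraction ``p**nC``; when
    given, the heavy monoisotopic area is understood to represent only
    that fraction of the spiked standard.  Returns NaN when the heavy
    area is zero (quantification failure for this peptide/sample).
    """
    if heavy_area <= 0:
        return float("nan")
    correction = 1.0 if deficit_correction is None else deficit_correction
    return (light_area / heavy_area) * meta.spiked_pmol * correction


def copies_per_cell(amount_pmol: float, cells: float) -> float:
    """Convert a molar amount in the digest to protein copies per cell."""
    if cells <= 0:
        raise QuantificationError("cell count must be positive")
    return amount_pmol * 1e-12 * AVOGADRO / cells


def protein_abundance(
    protein_id: str,
    peptide_copies: dict[str, float],
    exclusions: dict[str, str] | None = None,
) -> ProteinAbundance:
    """Average non-excluded peptide values into one protein abundance."""
    exclusions = exclusions or {}
    used = {
        pep: val
        for pep, val in peptide_copies.items()
        if pep not in exclusions and not np.isnan(val)
    }
    excluded = {pep: exclusions[pep] for pep in peptide_copies if pep in exclusions}
    for pep, val in peptide_copies.items():
        if pep not in exclusions and np.isnan(val):
            excluded[pep] = "quantification failure (zero heavy area)"
    if not used:
        raise QuantificationError(
            f"protein {protein_id!r}: all peptides excluded ({excluded})"
        )
    return ProteinAbundance(
        protein_id=protein_id,
        copies_per_cell=float(np.mean(list(used.values()))),
        per_peptide=dict(peptide_copies),
        peptides_used=sorted(used),
        peptides_excluded=excluded,
    )


def quantify_dataset(
    peaks: pd.DataFrame,
    meta: pd.DataFrame,
    peptide_to_protein: dict[str, str],
    enrichment: float = 0.99,
    deficit_correction: bool = True,
    exclusions: dict[str, str] | None = None,
    population_col: str = "population",
) -> pd.DataFrame:
    """Full pipeline: peak table + metadata -> copies/cell per protein.

    Replicate structure: abundances are computed per sample (replicate)
    and then averaged within each population; the reported SD is across
    replicates.  Returns a tidy frame with columns population, protein,
    copies_per_cell, sd, n_replicates, peptides_used, peptides_excluded.
    """
    meta_by_id = {
        row.sample_id: SampleMeta(
            sample_id=row.sample_id,
            spiked_pmol=row.spiked_pmol,
            total_protein_ug=row.total_protein_ug,
            cells_in_digest=row.cells_in_digest,
            is_negative_control=bool(row.is_negative_control),
        )
        for row in meta.itertuples()
    }
    populations = (
        dict(zip(meta["sample_id"], meta[population_col]))
        if population_col in meta.columns
        else {sid: "all" for sid in meta["sample_id"]}
    )
    control_ids = {sid for sid, m in meta_by_id.items() if m.is_negative_control}
    control = peaks[peaks["sample_id"].isin(control_ids)]
    samples = peaks[~peaks["sample_id"].isin(control_ids)]
    if not control.empty:
        samples = subtract_negative_control(samples, control)

    corrections = {
        pep: fully_labeled_fraction(elemental_composition(pep), enrichment)
        if deficit_correction
        else None
        for pep in peptide_to_protein
    }

    wide = samples.pivot_table(
        index=["sample_id", "peptide"], columns="channel", values="area"
    ).reset_index()
    per_sample: dict[tuple[str, str], dict[str, float]] = {}
    for row in wide.itertuples():
        if row.peptide not in peptide_to_protein:
            continue
        m = meta_by_id[row.sample_id]
        amount = quantify_peptide(
            getattr(row, "light", 0.0),
            getattr(row, "heavy", 0.0),
            m,
            corrections[row.peptide],
        )
        cpc = (
            copies_per_cell(amount, m.cells_in_digest)
            if not np.isnan(amount)
            else float("nan")
        )
        protein = peptide_to_protein[row.peptide]
        per_sample.setdefault((row.sample_id, protein), {})[row.peptide] = cpc

    records: dict[tuple[str, str], list[ProteinAbundance]] = {}
    for (sample_id, protein), peptide_values in sorted(per_sample.items()):
        ab = protein_abundance(protein, peptide_values, exclusions)
        records.setdefault((populations[sample_id], protein), []).append(ab)

    rows = []
    for (population, protein), abundances in sorted(records.items()):
        values = [a.copies_per_cell for a in abundances]
        rows.append(
            {
                "population": population,
                "protein": protein,
                "copies_per_cell": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
                "n_replicates": len(values),
                "peptides_used": ";".join(abundances[0].peptides_used),
                "peptides_excluded": ";".join(sorted(abundances[0].peptides_excluded)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC


def fit_calibration(
    points: list[tuple[float, float]],
    weighting: str = "none",
    peptide: str = "",
    residual_tol: float = 0.2,
) -> CalibrationCurve:
    """Least-squares line through (amount pmol, response ratio) points.

    ``weighting='inverse-amount'`` applies 1/x weights to the squared
    residuals (appropriate over the four-decade calibration range).  The
    validated range spans the points whose relative residual is below
    ``residual_tol``.
    """
    if len(points) < 2:
        raise QuantificationError("calibration needs at least 2 points")
    if weighting not in ("none", "inverse-amount"):
        raise ValueError("weighting must be 'none' or 'inverse-amount'")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    w = 1.0 / x if weighting == "inverse-amount" else np.ones_like(x)
    design = np.column_stack([x, np.ones_like(x)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    predicted = slope * x + intercept
    ss_res = float(np.sum((y - predicted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(predicted - y) / np.where(y == 0, np.nan, np.abs(y))
    ok = np.nan_to_num(rel, nan=np.inf) < residual_tol
    valid = x[ok] if ok.any() else x
    return CalibrationCurve(
        peptide=peptide,
        points=list(points),
        slope=slope,
        intercept=intercept,
        r_squared=min(1.0, r_squared),
        validated_range=(float(valid.min()), float(valid.max())),
    )


def digestion_plateau(
    timecourse: list[tuple[float, float]], rel_tol: float = 0.05
) -> PlateauResult:
    """Earliest time at which released signal stops increasing materially.

    Returns the first time t_i whose relative increase over t_{i-1} is
    below ``rel_tol``; if the signal never plateaus, the last time is
    returned flagged ``plateau_reached=False``.
    """
    if len(timecourse) < 3:
        raise QuantificationError("need at least 3 timepoints")
    times = [t for t, _ in timecourse]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise QuantificationError("times must be strictly increasing")
    for (t0, s0), (t1, s1) in zip(timecourse, timecourse[1:]):
        if s0 == 0:
            increase = 0.0 if s1 == 0 else float("inf")
        else:
            increase = (s1 - s0) / s0
        if increase < rel_tol:
            return PlateauResult(time_h=t1, plateau_reached=True)
    return PlateauResult(time_h=times[-1], plateau_reached=False)


def implied_molar_mass(mass_ug: float, amount_pmol: float) -> float:
    """Molar mass in kDa implied by a mass (ug) and molar amount (pmol)."""
    if mass_ug <= 0 or amount_pmol <= 0:
        raise QuantificationError("mass and amount must be positive")
    return mass_ug / amount_pmol * 1e3


def cells_in_digest_from_od(
    od_ml: float = 50.0,
    cells_per_od_ml: float = 8.0e8,
    aliquot_ug: float = 50.0,
    total_extracted_ug: float = 500.0,
) -> float:
    """Cells represented by a digest aliquot of the harvested extract.

    Harvest is expressed as OD600 x volume (mL); the per-OD-mL cell count
    (default 8e8, a standard E. coli rule of thumb) and the protein
    aliquot fraction scale it down to the digested share.
    """
    if min(od_ml, cells_per_od_ml, aliquot_ug, total_extracted_ug) <= 0:
        raise QuantificationError("all inputs must be positive")
    return od_ml * cells_per_od_ml * aliquot_ug / total_extracted_ug
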