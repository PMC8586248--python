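"""Peptide elemental compositions and isotopologue distributions.

The labeled QconCAT standard is produced on [U-13C6] glucose of finite
isotopic purity, so each of a peptide's ``nC`` carbons is 13C with
probability ``p`` (independently — metabolic label scrambling is
ignored).  The monoisotopic "heavy" peak then represents only the fully
labeled fraction ``p**nC``; the rest of the standard appears as a ladder
of labeling-deficit isotopologues at smaller mass.  Only carbon is
enriched; H, N, O and S stay at natural abundance, and isotopologues are
binned at unit (1 Da) resolution, the operating regime of a
triple-quadrupole instrument.

Natural-abundance constants are IUPAC 2013 representative values
(Meija et al., Pure Appl. Chem. 88, 2016).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics import mass as _pmass

from .seqdigest import _validate_sequence

NATURAL_13C = 0.0107

#: per-element single-atom isotopologue abundances, indexed by +k Da offset
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

_ELEMENTS = ("C", "H", "N", "O", "S")


@dataclass(frozen=True)
class ElementalComposition:
    """CHNOS atom counts of a peptide (or any molecule)."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        if min(self.c, self.h, self.n, self.o, self.s) < 0:
            raise ValueError("atom counts must be non-negative")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.c + other.c, self.h + other.h, self.n + other.n,
            self.o + other.o, self.s + other.s,
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.c - other.c, self.h - other.h, self.n - other.n,
            self.o - other.o, self.s - other.s,
        )

    def count(self, element: str) -> int:
        return getattr(self, element.lower())

    def monoisotopic_mass(self) -> float:
        return _pmass.calculate_mass(
            composition=_pmass.Composition(
                {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s}
            )
        )


WATER = ElementalComposition(h=2, o=1)


def elemental_composition(peptide: str) -> ElementalComposition:
    """CHNOS composition of a free peptide (residues plus one water)."""
    _validate_sequence(peptide, "peptide")
    comp = _pmass.Composition(sequence=peptide)
    extra = set(comp) - set(_ELEMENTS)
    if extra:  # cannot happen for canonical residues
        raise ValueError(f"unsupported elements: {sorted(extra)}")
    return ElementalComposition(
        c=comp.get("C", 0), h=comp.get("H", 0), n=comp.get("N", 0),
        o=comp.get("O", 0), s=comp.get("S", 0),
    )


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue abundances indexed by +k Da offsets from the base mass."""

    base_mass: float
    abundances: np.ndarray
    enrichment: float

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        if (a < 0).any():
            raise ValueError("abundances must be non-negative")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


def _n_fold_convolve(dist: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution by binary exponentiation."""
    result = np.array([1.0])
    power = dist
    while n:
        if n & 1:
            result = np.convolve(result, power)
        n >>= 1
        if n:
            power = np.convolve(power, power)
    return result


def isotope_pattern(
    comp: ElementalComposition, p: float = NATURAL_13C
) -> IsotopePattern:
    """Unit-resolution isotopologue distribution at 13C enrichment ``p``.

    Per-element distributions (carbon Bernoulli(p); H/N/O/S natural) are
    combined by discrete convolution, truncated once the cumulative
    abundance exceeds 1 - 1e-6, and renormalized.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("enrichment must be in [0, 1]")
    pattern = np.array([1.0])
    for element in _ELEMENTS:
        count = comp.count(element)
        if count == 0:
            continue
        if element == "C":
            single = np.array([1.0 - p, p])
        else:
            single = np.array(NATURAL_ABUNDANCE[element])
        pattern = np.convolve(pattern, _n_fold_convolve(single, count))
    cumulative = np.cumsum(pattern)
    cut = int(np.searchsorted(cumulative, 1.0 - 1e-6)) + 1
    pattern = pattern[:cut]
    pattern = pattern / pattern.sum()
    return IsotopePattern(
        base_mass=comp.monoisotopic_mass(), abundances=pattern, enrichment=p
    )


def fully_labeled_fraction(comp: ElementalComposition, p: float) -> float:
    """Probability that every carbon of a standard molecule is 13C."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("enrichment must be in [0, 1]")
    return p ** comp.c


def labeling_deficit_fraction(comp: ElementalComposition, p: float) -> float:
    """Probability a standard molecule is NOT fully 13C-labeled: 1 - p**nC."""
    return 1.0 - fully_labeled_fraction(comp, p)
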