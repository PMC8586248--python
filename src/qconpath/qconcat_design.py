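"""Concatamer (QconCAT) standard design and junction auditing.

A QconCAT standard concatenates the selected quantification peptides of
several target proteins into one artificial protein that is expressed
isotope-labeled and spiked into samples at a known molar amount.  Every
designed peptide must be released intact by trypsin, so each junction
between consecutive peptides is audited:

* ``blocked``  - the junction cannot be cleaved at all (left peptide does
  not end in K/R, or the right peptide starts with P), so the adjacent
  peptides are not released intact;
* ``acidic_neighbor`` - the residue after the cleavage site is D or E,
  which slows tryptic cleavage and makes a persistent junction-spanning
  missed-cleavage product likely;
* ``miscleavage_collision`` - such a spanning product is predicted among
  the digest products and overlaps a designed quantification peptide,
  biasing its heavy-standard signal; the affected (left) peptide should
  be excluded from quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

from .seqdigest import (
    CLEAVAGE_RESIDUES,
    PeptideSpec,
    ProteinRecord,
    SequenceError,
    _validate_sequence,
    digest,
)

ACIDIC_RESIDUES = frozenset("DE")

RISK_BLOCKED = "blocked"
RISK_ACIDIC = "acidic_neighbor"
RISK_COLLISION = "miscleavage_collision"


@dataclass(frozen=True)
class Junction:
    """Boundary between two adjacent segments of the concatamer."""

    index: int
    left: str
    right: str
    position: int  # index of the first residue of ``right`` in full_sequence

    @property
    def residues(self) -> str:
        return self.left[-1] + self.right[0]


@dataclass(frozen=True)
class ConcatamerDesign:
    name: str
    ordered_peptides: tuple[PeptideSpec, ...]
    leader_tag: str = ""
    trailer_tag: str = ""
    full_sequence: str = ""
    junctions: tuple[Junction, ...] = ()


@dataclass
class JunctionAudit:
    """Cleavability verdict and risk flags for one junction."""

    junction: Junction
    cleavable: bool
    risk_flags: list[str] = field(default_factory=list)
    spanning_peptide: str | None = None
    recommend_exclude: list[str] = field(default_factory=list)


def build_concatamer(
    peptides: list[PeptideSpec],
    leader_tag: str = "",
    trailer_tag: str = "",
    name: str = "qconcat",
) -> ConcatamerDesign:
    """Assemble peptides (plus optional tags) into a concatamer design."""
    if not peptides:
        raise SequenceError("concatamer needs at least one peptide")
    for tag in (leader_tag, trailer_tag):
        if tag:
            _validate_sequence(tag, "tag")
    segments = []
    if leader_tag:
        segments.append(leader_tag)
    segments.extend(p.sequence for p in peptides)
    if trailer_tag:
        segments.append(trailer_tag)
    full = "".join(segments)
    junctions = []
    pos = 0
    for i in range(len(segments) - 1):
        pos += len(segments[i])
        junctions.append(
            Junction(index=i, left=segments[i], right=segments[i + 1], position=pos)
        )
    return ConcatamerDesign(
        name=name,
        ordered_peptides=tuple(peptides),
        leader_tag=leader_tag,
        trailer_tag=trailer_tag,
        full_sequence=full,
        junctions=tuple(junctions),
    )


def protein_mass(sequence: str, kind: str = "monoisotopic") -> float:
    """Mass of a peptide/protein in Da (residue masses plus one water)."""
    if kind not in ("monoisotopic", "average"):
        raise ValueError("kind must be 'monoisotopic' or 'average'")
    average = kind == "average"
    if not sequence:  # zero residues: one water
        return _pmass.calculate_mass(composition={"H": 2, "O": 1}, average=average)
    _validate_sequence(sequence)
    return _pmass.calculate_mass(sequence=sequence, average=average)


def _design_protein(design: ConcatamerDesign) -> ProteinRecord:
    return ProteinRecord(id=design.name, sequence=design.full_sequence, role="other")


def releasable_peptides(design: ConcatamerDesign) -> set[str]:
    """Designed peptides that digest out of the concatamer fully cleaved."""
    products = {
        p.sequence
        for p in digest(_design_protein(design), max_missed=0)
    }
    return {p.sequence for p in design.ordered_peptides if p.sequence in products}


def audit_junctions(
    design: ConcatamerDesign, max_missed: int = 1
) -> list[JunctionAudit]:
    """Audit every junction of the design for release problems.

    Exclusion recommendations follow the slow-cleavage rule: when a
    junction-spanning missed-cleavage product is predicted to persist
    (acidic neighbor) or the junction is blocked outright, the designed
    peptide on the left of the junction cannot be trusted and is
    recommended for exclusion.
    """
    products = digest(_design_protein(design), max_missed=max_missed)
    spanning_products = {
        p.sequence for p in products if p.missed_cleavages >= 1
    }
    designed = {p.sequence for p in design.ordered_peptides}
    audits: list[JunctionAudit] = []
    for junction in design.junctions:
        left_last, right_first = junction.residues
        cleavable = left_last in CLEAVAGE_RESIDUES and right_first != "P"
        audit = JunctionAudit(junction=junction, cleavable=cleavable)
        spanning = junction.left + junction.right
        if not cleavable:
            audit.risk_flags.append(RISK_BLOCKED)
            if junction.left in designed:
                audit.recommend_exclude.append(junction.left)
        elif right_first in ACIDIC_RESIDUES:
            audit.risk_flags.append(RISK_ACIDIC)
            if spanning in spanning_products:
                audit.spanning_peptide = spanning
                if junction.left in designed or junction.right in designed:
                    audit.risk_flags.append(RISK_COLLISION)
                if junction.left in designed:
                    audit.recommend_exclude.append(junction.left)
        audits.append(audit)
    return audits


def recommended_exclusions(audits: list[JunctionAudit]) -> dict[str, str]:
    """Aggregate per-peptide exclusion reasons from a junction audit."""
    out: dict[str, str] = {}
    for audit in audits:
        for pep in audit.recommend_exclude:
            reason = (
                "junction blocked"
                if RISK_BLOCKED in audit.risk_flags
                else f"miscleavage at junction ({audit.spanning_peptide})"
            )
            out.setdefault(pep, reason)
    return out
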