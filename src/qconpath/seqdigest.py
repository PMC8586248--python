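"""In-silico tryptic digestion and quantification-peptide selection.

Trypsin cleaves C-terminal to K or R except when the next residue is
proline (Keil rule).  Peptides retaining internal cleavage sites are
"missed-cleavage" products; they matter here because a missed cleavage at
a concatamer junction biases quantification of the flanking peptides.

Coordinates are 0-based half-open throughout.  The residue preceding a
peptide's first position and the residue following its last position are
carried as cleavage context; protein termini are marked with dedicated
sentinels (:data:`N_TERMINUS`, :data:`C_TERMINUS`) rather than residue
letters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.SeqUtils.ProtParam import ProteinAnalysis

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
CLEAVAGE_RESIDUES = frozenset("KR")
#: sentinel context markers for protein termini
N_TERMINUS = "^"
C_TERMINUS = "$"

ROLES = ("P450", "CPR", "CDH", "other")


class FastaParseError(ValueError):
    """Malformed FASTA input (duplicate or unusable header)."""


class SequenceError(ValueError):
    """Sequence violates the canonical-residue or non-empty invariants."""


def _validate_sequence(seq: str, where: str = "sequence") -> str:
    if not seq:
        raise SequenceError(f"{where} is empty")
    bad = set(seq) - CANONICAL_RESIDUES
    if bad:
        raise SequenceError(
            f"{where} contains non-canonical residues: {sorted(bad)!r}"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A target protein: unique id, canonical sequence, pathway role."""

    id: str
    sequence: str
    role: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("protein id is empty")
        _validate_sequence(self.sequence, f"protein {self.id!r}")
        if self.role not in ROLES:
            raise SequenceError(
                f"protein {self.id!r}: unknown role {self.role!r}; "
                f"expected one of {ROLES}"
            )


@dataclass(frozen=True)
class PeptideSpec:
    """A tryptic peptide with provenance in its parent protein.

    ``missed_cleavages`` counts internal cleavage sites (per the Keil
    rule) retained inside the peptide.
    """

    sequence: str
    parent_id: str
    start: int
    end: int
    missed_cleavages: int
    n_term_context: str = N_TERMINUS
    c_term_context: str = C_TERMINUS

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence, f"peptide of {self.parent_id!r}")
        if self.end - self.start != len(self.sequence):
            raise SequenceError("peptide coordinates disagree with sequence length")
        if self.missed_cleavages < 0:
            raise SequenceError("missed_cleavages must be non-negative")


def cleavage_sites(sequence: str) -> list[int]:
    """Positions *after* which trypsin cleaves (0-based, exclusive ends).

    A site ``i`` means a cut between ``sequence[i-1]`` and ``sequence[i]``.
    Cleavage after K/R is suppressed when followed by P.
    """
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in CLEAVAGE_RESIDUES and sequence[i + 1] != "P"
    ]


def digest(protein: ProteinRecord, max_missed: int = 1) -> list[PeptideSpec]:
    """All tryptic peptides of ``protein`` with 0..``max_missed`` missed cleavages.

    Deterministic order: by (start, missed_cleavages).
    """
    if max_missed < 0 or max_missed > 3:
        raise ValueError("max_missed must be in 0..3")
    seq = protein.sequence
    bounds = [0, *cleavage_sites(seq), len(seq)]
    peptides: list[PeptideSpec] = []
    for a in range(len(bounds) - 1):
        for mc in range(max_missed + 1):
            b = a + 1 + mc
            if b >= len(bounds):
                break
            start, end = bounds[a], bounds[b]
            peptides.append(
                PeptideSpec(
                    sequence=seq[start:end],
                    parent_id=protein.id,
                    start=start,
                    end=end,
                    missed_cleavages=mc,
                    n_term_context=seq[start - 1] if start > 0 else N_TERMINUS,
                    c_term_context=seq[end] if end < len(seq) else C_TERMINUS,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def read_fasta(path, infer_roles: bool = True) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased and ``*`` stop symbols stripped.  When
    ``infer_roles`` is set, a ``role=<P450|CPR|CDH|other>`` tag anywhere in
    the header description assigns the pathway role.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        role = "other"
        if infer_roles:
            for token in entry.description.split():
                if token.startswith("role="):
                    role = token.split("=", 1)[1]
        seq = str(entry.seq).upper().replace("*", "")
        try:
            records.append(ProteinRecord(id=entry.id, sequence=seq, role=role))
        except SequenceError as exc:
            raise SequenceError(f"FASTA entry {entry.id!r}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# quantification-peptide selection


@dataclass(frozen=True)
class SelectionRules:
    """Configurable filters and scoring for quantification-peptide selection.

    The detection-strength proxy score favours mid-length peptides
    (8-15 residues), penalises histidines (variable charge states) and
    extreme hydropathy (poor retention or solubility).  It is a
    deterministic, documented stand-in for empirical LC-MS intensity.
    """

    min_length: int = 6
    max_length: int = 25
    disallowed_residues: str = "MC"
    forbidden_motifs: tuple[str, ...] = ("NG",)
    reject_ragged_ends: bool = True
    require_unique: bool = True
    top_k: int = 2
    preferred_length: tuple[int, int] = (8, 15)
    histidine_penalty: float = 0.2
    gravy_limit: float = 1.5
    gravy_penalty: float = 0.5


@dataclass
class PeptideCandidate:
    """A fully-cleaved peptide with its selection verdict."""

    peptide: PeptideSpec
    passed: bool
    reasons: list[str] = field(default_factory=list)
    score: float = 0.0
    selected: bool = False


def detection_strength_score(sequence: str, rules: SelectionRules) -> float:
    lo, hi = rules.preferred_length
    n = len(sequence)
    if lo <= n <= hi:
        length_score = 1.0
    else:
        length_score = max(0.0, 1.0 - 0.15 * min(abs(n - lo), abs(n - hi)))
    gravy = ProteinAnalysis(sequence).gravy()
    score = length_score
    score -= rules.histidine_penalty * sequence.count("H")
    score -= rules.gravy_penalty * max(0.0, abs(gravy) - rules.gravy_limit)
    return score


def _rejection_reasons(
    pep: PeptideSpec,
    parent: ProteinRecord,
    all_sequences: dict[str, str],
    rules: SelectionRules,
) -> list[str]:
    reasons: list[str] = []
    seq = pep.sequence
    if not (rules.min_length <= len(seq) <= rules.max_length):
        reasons.append("length")
    if any(r in seq for r in rules.disallowed_residues):
        reasons.append("excluded residue")
    if any(m in seq for m in rules.forbidden_motifs):
        reasons.append("unstable motif")
    if rules.reject_ragged_ends:
        before_context = (
            parent.sequence[pep.start - 2] if pep.start >= 2 else N_TERMINUS
        )
        ragged_n = before_context in CLEAVAGE_RESIDUES
        ragged_c = pep.c_term_context in CLEAVAGE_RESIDUES
        if ragged_n or ragged_c:
            reasons.append("ragged end")
    if rules.require_unique:
        hits = sum(s.count(seq) for s in all_sequences.values())
        if hits > 1:
            reasons.append("not unique")
    return reasons


def select_qpeptides(
    proteins: list[ProteinRecord],
    rules: SelectionRules | None = None,
) -> dict[str, list[PeptideCandidate]]:
    """Rank fully-cleaved peptides of each protein as quantification candidates.

    Returns, per protein id, all 0-missed-cleavage peptides with
    machine-readable rejection reasons; passing candidates are ranked by
    the detection-strength proxy and the top-k flagged ``selected``.
    A protein with zero passing candidates yields a warning, not an error.
    """
    rules = rules or SelectionRules()
    all_sequences = {p.id: p.sequence for p in proteins}
    if len(all_sequences) != len(proteins):
        raise SequenceError("protein ids are not unique")
    out: dict[str, list[PeptideCandidate]] = {}
    for protein in proteins:
        candidates = []
        for pep in digest(protein, max_missed=0):
            reasons = _rejection_reasons(pep, protein, all_sequences, rules)
            candidates.append(
                PeptideCandidate(
                    peptide=pep,
                    passed=not reasons,
                    reasons=reasons,
                    score=detection_strength_score(pep.sequence, rules),
                )
            )
        passing = sorted(
            (c for c in candidates if c.passed),
            key=lambda c: (-c.score, c.peptide.sequence),
        )
        for c in passing[: rules.top_k]:
            c.selected = True
        if not passing:
            warnings.warn(
                f"protein {protein.id!r}: no peptide passes the selection filters",
                stacklevel=2,
            )
        candidates.sort(key=lambda c: (-c.passed, -c.score, c.peptide.start))
        out[protein.id] = candidates
    return out


def reselect(peptide: PeptideSpec, proteins: list[ProteinRecord]) -> PeptideSpec:
    """Re-anchor a peptide sequence in its parent (used by fixtures)."""
    by_id = {p.id: p for p in proteins}
    parent = by_id[peptide.parent_id]
    for pep in digest(parent, max_missed=0):
        if pep.sequence == peptide.sequence:
            return pep
    raise SequenceError(
        f"{peptide.sequence} is not a fully-cleaved peptide of {parent.id}"
    )
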