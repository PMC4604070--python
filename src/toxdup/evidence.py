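"""Proteome detection from identified peptides, and contaminant screening.

A protein counts as detected when at least ``min_peptides`` distinct
observed peptides each place on it with ungapped identity strictly above
``min_identity``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats import HitRecord, SequenceRecord

__all__ = [
    "PeptideMatch",
    "tryptic_digest",
    "best_peptide_identity",
    "detect_proteins",
    "peptide_support",
    "screen_contaminants",
]


@dataclass(frozen=True)
class PeptideMatch:
    peptide: str
    protein_id: str
    identity: float
    placement_start: int  # 0-based offset of the best placement

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be within [0, 1]")
        if self.placement_start < 0:
            raise ValueError("placement outside protein bounds")


def tryptic_digest(protein: SequenceRecord | str, max_missed: int = 3) -> list[str]:
    """In-silico tryptic peptides with up to ``max_missed`` missed cleavages.

    Trypsin cuts after K or R except when the next residue is P.  The
    0-missed peptides concatenate back to the input sequence; peptides
    spanning up to ``max_missed`` internal cleavage sites are added, ordered
    by start position then length.
    """
    seq = protein.residues if isinstance(protein, SequenceRecord) else protein
    if not seq:
        raise ValueError("empty protein sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cuts = [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + cuts + [len(seq)]
    pieces = [seq[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides: list[str] = []  # ordered by start offset, then length
    for start in range(len(pieces)):
        for span in range(1, max_missed + 2):
            if start + span > len(pieces):
                break
            peptides.append("".join(pieces[start : start + span]))
    return peptides


def best_peptide_identity(peptide: str, protein: SequenceRecord) -> PeptideMatch:
    """Ungapped sliding-window identity at the best offset (ties: smallest).

    Raises when the peptide is longer than the protein.
    """
    target = protein.residues
    if not peptide:
        raise ValueError("empty peptide")
    if len(peptide) > len(target):
        raise ValueError(
            f"peptide longer than protein {protein.id!r} "
            f"({len(peptide)} > {len(target)})"
        )
    best_matches, best_offset = -1, 0
    for offset in range(len(target) - len(peptide) + 1):
        matches = sum(
            1 for a, b in zip(peptide, target[offset : offset + len(peptide)]) if a == b
        )
        if matches > best_matches:
            best_matches, best_offset = matches, offset
    return PeptideMatch(
        peptide=peptide,
        protein_id=protein.id,
        identity=best_matches / len(peptide),
        placement_start=best_offset,
    )


def peptide_support(
    observed_peptides: Iterable[str],
    proteins: Sequence[SequenceRecord],
    min_identity: float = 0.95,
) -> dict[str, list[PeptideMatch]]:
    """Per-protein supporting matches with identity strictly above the
    threshold.  Distinct peptides are counted by sequence string."""
    unique = sorted(set(observed_peptides))
    support: dict[str, list[PeptideMatch]] = {}
    for prot in proteins:
        matches = []
        for pep in unique:
            if len(pep) > len(prot.residues):
                continue
            match = best_peptide_identity(pep, prot)
            if match.identity > min_identity:
                matches.append(match)
        if matches:
            support[prot.id] = matches
    return support


def detect_proteins(
    observed_peptides: Iterable[str],
    proteins: Sequence[SequenceRecord],
    min_identity: float = 0.95,
    min_peptides: int = 2,
) -> set[str]:
    """Proteins supported by >= ``min_peptides`` distinct peptides, each at
    identity strictly greater than ``min_identity``.  A peptide may support
    several proteins."""
    support = peptide_support(observed_peptides, proteins, min_identity)
    return {pid for pid, matches in support.items() if len(matches) >= min_peptides}


def screen_contaminants(
    detected: set[str],
    contaminant_hits: Sequence[HitRecord],
    evalue_cutoff: float = 1.0e-20,
) -> set[str]:
    """Flag detected proteins with a contaminant-proteome hit strictly below
    the e-value cutoff.  A clean run returns the empty set."""
    return {
        h.query_id
        for h in contaminant_hits
        if h.query_id in detected and h.evalue < evalue_cutoff
    }
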