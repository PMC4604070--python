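"""Readers and writers for the plain-text formats the toolkit consumes.

Formats handled here:

* FASTA (sequences and gapped multiple alignments),
* 13-column tab-separated homology hit tables (the classic 12-column
  tabular dialect plus an appended query-coverage column),
* tab-separated per-protein annotation tables (with header),
* plain-text peptide lists (one peptide per line),
* Newick serialisation of labelled trees.

Every reader validates its type invariants and raises :class:`FormatError`
with a file/line location instead of silently coercing bad input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "SequenceRecord",
    "Alignment",
    "HitRecord",
    "AnnotationRecord",
    "TreeNode",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_hit_table",
    "write_hit_table",
    "read_annotations",
    "write_annotations",
    "read_peptides",
    "write_peptides",
    "write_newick",
]

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

# characters tolerated in residue strings (protein, nucleotide, binary
# coalescent states) before gap normalisation
_RESIDUE_RE = re.compile(r"^[A-Za-z0-9.\-*?]+$")


class FormatError(ValueError):
    """A file violated a format or type invariant; message carries location."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: unique ``id``, free-text ``description``, residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has empty residues")
        if not _RESIDUE_RE.match(self.residues):
            raise FormatError(f"sequence record {self.id!r} has invalid characters")

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class Alignment:
    """A rectangular multiple alignment; gap character is ``-``."""

    members: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError("alignment with no rows")
        width = len(self.members[0].residues)
        for rec in self.members:
            if len(rec.residues) != width:
                raise FormatError(
                    f"alignment row {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {width}"
                )
            if set(rec.residues) <= {GAP}:
                raise FormatError(f"alignment row {rec.id!r} is all gaps")
        ids = [rec.id for rec in self.members]
        if len(set(ids)) != len(ids):
            raise FormatError("alignment contains duplicate row ids")

    @property
    def n_rows(self) -> int:
        return len(self.members)

    @property
    def n_cols(self) -> int:
        return len(self.members[0].residues)

    def ids(self) -> list[str]:
        return [rec.id for rec in self.members]

    def column(self, j: int) -> str:
        return "".join(rec.residues[j] for rec in self.members)

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "Alignment":
        return cls(tuple(records))


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular homology-search result.

    ``query_coverage`` is stored as a fraction in [0, 1]; ``rank`` is the
    1-based rank of the subject among the query's hits ordered by ascending
    e-value (ties: higher bitscore, then lexicographic subject id).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    query_coverage: float
    rank: int = 1

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: negative e-value")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: query coverage "
                f"{self.query_coverage} outside [0, 1]"
            )
        if self.rank < 1:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: rank < 1")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-protein annotation consumed by the structural filter."""

    protein_id: str
    tm_count: int = 0
    domain_ok: bool = True
    go_excluded: bool = False
    is_toxin_subject: bool = False

    def __post_init__(self) -> None:
        if self.tm_count < 0:
            raise FormatError(f"annotation {self.protein_id!r}: tm_count < 0")


@dataclass
class TreeNode:
    """Rooted tree node; leaves carry labels, edges carry lengths."""

    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label] if self.label is not None else [None]  # type: ignore[list-item]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaf_labels())
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file into records, preserving order.

    '.' gap characters are normalised to '-'.  Duplicate ids and empty
    sequences raise :class:`FormatError` with a location.
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        residues = "".join(chunks).replace(".", GAP)
        if not residues:
            raise FormatError(f"{path}:{header_line}: record {header!r} has no sequence")
        parts = header.split(None, 1)
        rid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        if rid in seen:
            raise FormatError(
                f"{path}:{header_line}: duplicate sequence id {rid!r} "
                f"(first seen at line {seen[rid]})"
            )
        seen[rid] = header_line
        try:
            records.append(SequenceRecord(id=rid, residues=residues, description=desc))
        except FormatError as exc:
            raise FormatError(f"{path}:{header_line}: {exc}") from exc

    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence data before first header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 60) -> None:
    """Write records as FASTA with residues wrapped at ``width`` columns."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file; all rows must have equal length."""
    try:
        return Alignment.from_records(read_fasta(path))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_alignment(alignment: Alignment, path, width: int = 60) -> None:
    write_fasta(alignment.members, path, width=width)


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = 13


def _parse_float(token: str, path, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric {what} {token!r}") from None


def _parse_int(token: str, path, lineno: int, what: str) -> int:
    try:
        return int(float(token))
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric {what} {token!r}") from None


def assign_ranks(hits: Sequence[HitRecord]) -> list[HitRecord]:
    """Recompute per-query ranks by ascending e-value.

    Ties are broken by descending bitscore then lexicographic subject id,
    so the ranking is independent of input order.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for hit in hits:
        by_query.setdefault(hit.query_id, []).append(hit)
    out: list[HitRecord] = []
    for qid in sorted(by_query):
        ordered = sorted(
            by_query[qid], key=lambda h: (h.evalue, -h.bitscore, h.subject_id)
        )
        for rank, hit in enumerate(ordered, start=1):
            out.append(
                HitRecord(
                    query_id=hit.query_id,
                    subject_id=hit.subject_id,
                    percent_identity=hit.percent_identity,
                    alignment_length=hit.alignment_length,
                    mismatches=hit.mismatches,
                    gap_opens=hit.gap_opens,
                    q_start=hit.q_start,
                    q_end=hit.q_end,
                    s_start=hit.s_start,
                    s_end=hit.s_end,
                    evalue=hit.evalue,
                    bitscore=hit.bitscore,
                    query_coverage=hit.query_coverage,
                    rank=rank,
                )
            )
    return out


def read_hit_table(
    path,
    coverage_unit: str = "fraction",
    skip_header: bool = False,
) -> list[HitRecord]:
    """Parse a 13-column tab-separated hit table.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, q.start, q.end, s.start, s.end, e-value, bitscore, query coverage.
    ``coverage_unit`` is ``"fraction"`` (default) or ``"percent"`` (divided
    by 100 on read).  Ranks are recomputed from e-value ordering.
    """
    if coverage_unit not in ("fraction", "percent"):
        raise ValueError(f"unknown coverage_unit {coverage_unit!r}")
    hits: list[HitRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            if skip_header and lineno == 1:
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            coverage = _parse_float(fields[12], path, lineno, "query coverage")
            if coverage_unit == "percent":
                coverage /= 100.0
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=_parse_float(fields[2], path, lineno, "identity"),
                        alignment_length=_parse_int(fields[3], path, lineno, "length"),
                        mismatches=_parse_int(fields[4], path, lineno, "mismatches"),
                        gap_opens=_parse_int(fields[5], path, lineno, "gap opens"),
                        q_start=_parse_int(fields[6], path, lineno, "q.start"),
                        q_end=_parse_int(fields[7], path, lineno, "q.end"),
                        s_start=_parse_int(fields[8], path, lineno, "s.start"),
                        s_end=_parse_int(fields[9], path, lineno, "s.end"),
                        evalue=_parse_float(fields[10], path, lineno, "e-value"),
                        bitscore=_parse_float(fields[11], path, lineno, "bitscore"),
                        query_coverage=coverage,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return assign_ranks(hits)


def write_hit_table(hits: Sequence[HitRecord], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        repr(h.percent_identity),
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        repr(h.evalue),
                        repr(h.bitscore),
                        repr(h.query_coverage),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

_ANN_HEADER = ["protein_id", "tm_count", "domain_ok", "go_excluded", "is_toxin_subject"]
_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f"}


def _parse_bool(token: str, path, lineno: int, what: str) -> bool:
    lowered = token.strip().lower()
    if lowered in _TRUE:
        return True
    if lowered in _FALSE:
        return False
    raise FormatError(f"{path}:{lineno}: non-boolean {what} {token!r}")


def read_annotations(path) -> dict[str, AnnotationRecord]:
    """Read a header-bearing TSV annotation table keyed by protein id."""
    records: dict[str, AnnotationRecord] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ANN_HEADER:
            raise FormatError(
                f"{path}:1: expected header {_ANN_HEADER}, found {header}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_ANN_HEADER):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_ANN_HEADER)} columns, "
                    f"found {len(fields)}"
                )
            pid = fields[0]
            if pid in records:
                raise FormatError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            records[pid] = AnnotationRecord(
                protein_id=pid,
                tm_count=_parse_int(fields[1], path, lineno, "tm_count"),
                domain_ok=_parse_bool(fields[2], path, lineno, "domain_ok"),
                go_excluded=_parse_bool(fields[3], path, lineno, "go_excluded"),
                is_toxin_subject=_parse_bool(fields[4], path, lineno, "is_toxin_subject"),
            )
    return records


def write_annotations(records: dict[str, AnnotationRecord], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_ANN_HEADER) + "\n")
        for pid in sorted(records):
            r = records[pid]
            fh.write(
                f"{r.protein_id}\t{r.tm_count}\t{int(r.domain_ok)}\t"
                f"{int(r.go_excluded)}\t{int(r.is_toxin_subject)}\n"
            )


# ---------------------------------------------------------------------------
# Peptide lists
# ---------------------------------------------------------------------------

def read_peptides(path) -> list[str]:
    """Read a plain-text peptide list, one peptide per line."""
    peptides: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            pep = raw.strip()
            if not pep:
                continue
            if not pep.isalpha():
                raise FormatError(f"{path}:{lineno}: invalid peptide {pep!r}")
            peptides.append(pep.upper())
    return peptides


def write_peptides(peptides: Sequence[str], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for pep in peptides:
            fh.write(pep + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _format_length(x: float) -> str:
    if x < 0:
        raise FormatError(f"negative branch length {x}")
    return format(x, ".6g")


def _newick_node(node: TreeNode, with_length: bool) -> str:
    if node.is_leaf:
        if not node.label:
            raise FormatError("unlabelled leaf in tree")
        text = node.label
    else:
        # deterministic child order: lexicographic by smallest leaf label
        ordered = sorted(
            node.children, key=lambda c: min(x or "" for x in c.leaf_labels())
        )
        text = "(" + ",".join(_newick_node(c, True) for c in ordered) + ")"
    if with_length:
        text += ":" + _format_length(node.length)
    return text


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree to a Newick string with deterministic child order."""
    return _newick_node(tree, with_length=False) + ";"
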