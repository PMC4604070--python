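"""The five-stage candidate-toxin filter.

Stage 0 recovers proteins with a sub-threshold homology hit against the
toxin database; stages 1-5 then successively demand (1) a strict or relaxed
reciprocal best hit to the toxin database with high query coverage, (2)
reciprocal support in both a supplemented full protein database and a
taxon-restricted database, (3) score consistency (no non-toxin subject
outscoring every toxin subject), (4) a toxin-compatible structure
(transmembrane count, domain architecture, GO terms), and (5) confident
support in the organism's own translated genome.

All thresholds are strict inequalities; boundary values fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats import AnnotationRecord, HitRecord

__all__ = [
    "PipelineConfig",
    "CandidateToxin",
    "FilterReport",
    "PipelineInputs",
    "compute_rbbh",
    "compute_relaxed_rbbh",
    "stage0_evalue_filter",
    "stage1_toxdb_filter",
    "stage2_dual_database_filter",
    "stage3_consistency_filter",
    "stage4_structure_filter",
    "stage5_genome_support_filter",
    "run_pipeline",
]

STAGE_REASONS = (
    "evalue",
    "no_rbbh",
    "coverage",
    "inconsistent",
    "structure",
    "no_paralog_support",
)


@dataclass(frozen=True)
class PipelineConfig:
    evalue_initial: float = 1.0e-5
    qcov_stage1: float = 0.70
    evalue_stage2: float = 1.0e-5
    relaxed_k: int = 5
    qcov_stage5: float = 0.75
    evalue_stage5: float = 1.0e-20
    exclude_self_hits: bool = False
    missing_annotation_rejects: bool = True
    stage3_by_evalue: bool = False  # alternative: rank subjects by e-value

    def __post_init__(self) -> None:
        for name in ("evalue_initial", "evalue_stage2", "evalue_stage5"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("qcov_stage1", "qcov_stage5"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.relaxed_k < 1:
            raise ValueError("relaxed_k must be >= 1")


@dataclass(frozen=True)
class CandidateToxin:
    """One protein's passage record.  ``stage_reached`` is the last stage
    cleared (0-5); floor 0 is also used for stage-0 failures, which are
    distinguished by ``rejection_reason == "evalue"``."""

    protein_id: str
    stage_reached: int
    passed: bool
    best_toxin_hit: HitRecord | None = None
    rejection_reason: str | None = None

    def __post_init__(self) -> None:
        if self.passed != (self.stage_reached == 5 and self.rejection_reason is None):
            raise ValueError("pass flag inconsistent with stage_reached/reason")
        if (self.rejection_reason is None) != self.passed:
            raise ValueError("rejection_reason must be set iff not passed")
        if self.rejection_reason is not None and self.rejection_reason not in STAGE_REASONS:
            raise ValueError(f"unknown rejection reason {self.rejection_reason!r}")


@dataclass
class FilterReport:
    stage_counts: list[tuple[str, int, int]]  # (stage name, n_in, n_out)
    candidates: list[CandidateToxin] = field(default_factory=list)

    def passed_ids(self) -> list[str]:
        return sorted(c.protein_id for c in self.candidates if c.passed)


@dataclass
class PipelineInputs:
    """All hit/annotation tables the pipeline consumes."""

    hits_toxdb: list[HitRecord]
    hits_toxdb_rev: list[HitRecord]
    hits_fulldb: list[HitRecord]
    hits_fulldb_rev: list[HitRecord]
    hits_cniddb: list[HitRecord]
    hits_cniddb_rev: list[HitRecord]
    hits_selfgenome: list[HitRecord]
    annotations: dict[str, AnnotationRecord]


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def _best_subjects(hits: Iterable[HitRecord], k: int) -> dict[str, list[str]]:
    """Top-``k`` subject ids per query, ordered by (evalue, -bitscore, id)."""
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return {
        q: [
            h.subject_id
            for h in sorted(rows, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))[:k]
        ]
        for q, rows in by_query.items()
    }


def compute_rbbh(
    hits_ab: Sequence[HitRecord], hits_ba: Sequence[HitRecord]
) -> set[tuple[str, str]]:
    """Strict reciprocal best hits: ``(a, b)`` iff each is the other's rank-1
    subject (ties broken by higher bitscore, then lexicographic id)."""
    best_ab = _best_subjects(hits_ab, 1)
    best_ba = _best_subjects(hits_ba, 1)
    return {
        (a, subs[0])
        for a, subs in best_ab.items()
        if subs and best_ba.get(subs[0], [None])[0] == a
    }


def compute_relaxed_rbbh(
    hits_ab: Sequence[HitRecord], hits_ba: Sequence[HitRecord], k: int = 5
) -> set[tuple[str, str]]:
    """Relaxed reciprocal hits: ``(a, b)`` iff b is within a's top ``k``
    subjects and a within b's top ``k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    top_ab = _best_subjects(hits_ab, k)
    top_ba = _best_subjects(hits_ba, k)
    out: set[tuple[str, str]] = set()
    for a, subs in top_ab.items():
        for b in subs:
            if a in top_ba.get(b, ()):
                out.add((a, b))
    return out


def _reciprocal_pairs(
    fwd: Sequence[HitRecord], rev: Sequence[HitRecord], k: int
) -> set[tuple[str, str]]:
    return compute_rbbh(fwd, rev) | compute_relaxed_rbbh(fwd, rev, k)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage0_evalue_filter(
    hits: Sequence[HitRecord], cfg: PipelineConfig
) -> set[str]:
    """Proteins with at least one hit below the initial e-value cutoff."""
    return {h.query_id for h in hits if h.evalue < cfg.evalue_initial}


def best_toxin_hit(
    protein: str, hits: Sequence[HitRecord]
) -> HitRecord | None:
    rows = [h for h in hits if h.query_id == protein]
    if not rows:
        return None
    return min(rows, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def stage1_toxdb_filter(
    proteins: set[str],
    hits_toxdb: Sequence[HitRecord],
    hits_toxdb_rev: Sequence[HitRecord],
    cfg: PipelineConfig,
) -> set[str]:
    """Keep proteins with a (strict or relaxed) reciprocal hit to the toxin
    database whose best toxin hit has query coverage strictly above the
    stage-1 threshold."""
    pairs = _reciprocal_pairs(hits_toxdb, hits_toxdb_rev, cfg.relaxed_k)
    reciprocal = {a for a, _ in pairs}
    out = set()
    for p in proteins & reciprocal:
        best = best_toxin_hit(p, hits_toxdb)
        if best is not None and best.query_coverage > cfg.qcov_stage1:
            out.add(p)
    return out


def _qualifies_in_db(
    protein: str,
    fwd: Sequence[HitRecord],
    rev: Sequence[HitRecord],
    cfg: PipelineConfig,
) -> bool:
    pairs = _reciprocal_pairs(fwd, rev, cfg.relaxed_k)
    partners = {b for a, b in pairs if a == protein}
    if not partners:
        return False
    for h in fwd:
        if h.query_id == protein and h.subject_id in partners:
            if h.evalue < cfg.evalue_stage2:
                return True
    return False


def stage2_dual_database_filter(
    proteins: set[str],
    hits_fulldb: Sequence[HitRecord],
    hits_fulldb_rev: Sequence[HitRecord],
    hits_cniddb: Sequence[HitRecord],
    hits_cniddb_rev: Sequence[HitRecord],
    cfg: PipelineConfig,
) -> set[str]:
    """Keep proteins with qualifying reciprocal hits (e-value strictly below
    the stage-2 cutoff) in BOTH databases."""
    return {
        p
        for p in proteins
        if _qualifies_in_db(p, hits_fulldb, hits_fulldb_rev, cfg)
        and _qualifies_in_db(p, hits_cniddb, hits_cniddb_rev, cfg)
    }


def stage3_consistency_filter(
    proteins: set[str],
    hits_fulldb: Sequence[HitRecord],
    annotations: dict[str, AnnotationRecord],
    cfg: PipelineConfig | None = None,
) -> set[str]:
    """Discard proteins whose best non-toxin subject strictly outscores their
    best toxin subject in the supplemented full database.

    Subjects missing from the annotation table count as non-toxin.  A
    protein with no toxin-subject hit at all is discarded.  Ties retain.
    """
    cfg = cfg or PipelineConfig()
    out = set()
    for p in proteins:
        rows = [h for h in hits_fulldb if h.query_id == p]
        if cfg.stage3_by_evalue:
            score = lambda h: -h.evalue  # noqa: E731 - higher is better
        else:
            score = lambda h: h.bitscore  # noqa: E731
        toxin = [
            score(h)
            for h in rows
            if annotations.get(h.subject_id) is not None
            and annotations[h.subject_id].is_toxin_subject
        ]
        non_toxin = [
            score(h)
            for h in rows
            if not (
                annotations.get(h.subject_id) is not None
                and annotations[h.subject_id].is_toxin_subject
            )
        ]
        if not toxin:
            continue  # no toxin support: discarded
        if non_toxin and max(non_toxin) > max(toxin):
            continue
        out.add(p)
    return out


def stage4_structure_filter(
    proteins: set[str],
    annotations: dict[str, AnnotationRecord],
    cfg: PipelineConfig | None = None,
) -> set[str]:
    """Discard proteins with >= 2 predicted transmembrane segments, a
    non-toxin domain architecture, or an excluded GO term.  Missing
    annotation records reject by default (fail closed)."""
    cfg = cfg or PipelineConfig()
    out = set()
    for p in proteins:
        ann = annotations.get(p)
        if ann is None:
            if not cfg.missing_annotation_rejects:
                out.add(p)
            continue
        if ann.tm_count >= 2 or not ann.domain_ok or ann.go_excluded:
            continue
        out.add(p)
    return out


def stage5_genome_support_filter(
    proteins: set[str],
    hits_selfgenome: Sequence[HitRecord],
    cfg: PipelineConfig,
) -> set[str]:
    """Keep proteins with a translated-genome hit of coverage strictly above
    and e-value strictly below the stage-5 thresholds."""
    out = set()
    for h in hits_selfgenome:
        if h.query_id not in proteins:
            continue
        if cfg.exclude_self_hits and h.subject_id == h.query_id:
            continue
        if h.query_coverage > cfg.qcov_stage5 and h.evalue < cfg.evalue_stage5:
            out.add(h.query_id)
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(inputs: PipelineInputs, cfg: PipelineConfig | None = None) -> FilterReport:
    """Run all stages and produce per-protein passage records.

    The pipeline is a pure function of its inputs: identical calls yield
    identical reports.
    """
    cfg = cfg or PipelineConfig()
    universe = sorted({h.query_id for h in inputs.hits_toxdb})

    s0 = stage0_evalue_filter(inputs.hits_toxdb, cfg)
    s1 = stage1_toxdb_filter(s0, inputs.hits_toxdb, inputs.hits_toxdb_rev, cfg)
    s2 = stage2_dual_database_filter(
        s1,
        inputs.hits_fulldb,
        inputs.hits_fulldb_rev,
        inputs.hits_cniddb,
        inputs.hits_cniddb_rev,
        cfg,
    )
    s3 = stage3_consistency_filter(s2, inputs.hits_fulldb, inputs.annotations, cfg)
    s4 = stage4_structure_filter(s3, inputs.annotations, cfg)
    s5 = stage5_genome_support_filter(s4, inputs.hits_selfgenome, cfg)

    stages = [
        ("stage0_evalue", len(universe), len(s0)),
        ("stage1_toxdb_rbbh", len(s0), len(s1)),
        ("stage2_dual_db", len(s1), len(s2)),
        ("stage3_consistency", len(s2), len(s3)),
        ("stage4_structure", len(s3), len(s4)),
        ("stage5_genome_support", len(s4), len(s5)),
    ]

    # stage-1 failures split into missing reciprocity vs low coverage
    stage1_pairs = _reciprocal_pairs(inputs.hits_toxdb, inputs.hits_toxdb_rev, cfg.relaxed_k)
    stage1_reciprocal = {a for a, _ in stage1_pairs}

    candidates: list[CandidateToxin] = []
    for p in universe:
        best = best_toxin_hit(p, inputs.hits_toxdb)
        if p not in s0:
            record = CandidateToxin(p, 0, False, best, "evalue")
        elif p not in s1:
            reason = "no_rbbh" if p not in stage1_reciprocal else "coverage"
            record = CandidateToxin(p, 0, False, best, reason)
        elif p not in s2:
            record = CandidateToxin(p, 1, False, best, "no_rbbh")
        elif p not in s3:
            record = CandidateToxin(p, 2, False, best, "inconsistent")
        elif p not in s4:
            record = CandidateToxin(p, 3, False, best, "structure")
        elif p not in s5:
            record = CandidateToxin(p, 4, False, best, "no_paralog_support")
        else:
            record = CandidateToxin(p, 5, True, best)
        candidates.append(record)

    return FilterReport(stage_counts=stages, candidates=candidates)
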