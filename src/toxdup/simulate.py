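"""Seeded generators for every input the analysis modules consume.

Each generator is a pure function of its parameters and seed and emits the
planted ground truth alongside the dataset.  The truth object is consumed
only by tests and reports, never by the code under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evidence import tryptic_digest
from .formats import (
    Alignment,
    AnnotationRecord,
    HitRecord,
    SequenceRecord,
)
from .pipeline import PipelineInputs

__all__ = [
    "FamilySimSpec",
    "PlantedTruth",
    "simulate_family_set",
    "simulate_neutral_alignment",
    "simulate_pipeline_fixture",
    "simulate_peptide_observations",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilySimSpec:
    """Parameters for a planted family-of-duplicates simulation.

    ``substitution_prob`` is either a per-site probability applied on every
    ancestor->member edge, or a ``(lo, hi)`` range sampled once per family.
    """

    n_families: int = 3
    members_per_family: int = 4
    ancestor_length: int = 50
    substitution_prob: float | tuple[float, float] = 0.10
    n_decoys: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.substitution_prob
            if isinstance(self.substitution_prob, tuple)
            else (self.substitution_prob,)
        )
        for p in probs:
            if not 0.0 <= p < 1.0:
                raise ValueError("substitution probability must be in [0, 1)")
        for name in ("n_families", "members_per_family", "ancestor_length", "n_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PlantedTruth:
    """Ground-truth labels accompanying a generated dataset."""

    labels: dict[str, str] = field(default_factory=dict)  # id -> family or "decoy"
    failing: dict[str, str | None] = field(default_factory=dict)  # id -> reason
    detectable: set[str] = field(default_factory=set)
    expected_stage_counts: list[tuple[str, int, int]] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def _mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    out = list(seq)
    mask = rng.random(len(seq)) < p
    for i in np.flatnonzero(mask):
        current = _AA.index(out[i])
        # uniform replacement over the 19 alternative residues
        alt = int(rng.integers(0, len(_AA) - 1))
        if alt >= current:
            alt += 1
        out[i] = _AA[alt]
    return "".join(out)


def simulate_family_set(spec: FamilySimSpec) -> tuple[list[SequenceRecord], PlantedTruth]:
    """Families of duplicated sequences plus unrelated decoys.

    Each family is a uniform-random ancestor whose members mutate
    independently, star-wise, at the spec'd per-site probability.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truth = PlantedTruth()
    for f in range(1, spec.n_families + 1):
        ancestor = _random_sequence(rng, spec.ancestor_length)
        if isinstance(spec.substitution_prob, tuple):
            lo, hi = spec.substitution_prob
            p = float(rng.uniform(lo, hi))
        else:
            p = spec.substitution_prob
        for m in range(1, spec.members_per_family + 1):
            sid = f"fam{f}m{m}"
            records.append(
                SequenceRecord(id=sid, residues=_mutate(rng, ancestor, p))
            )
            truth.labels[sid] = f"fam{f}"
    for d in range(1, spec.n_decoys + 1):
        sid = f"decoy{d:02d}"
        records.append(
            SequenceRecord(id=sid, residues=_random_sequence(rng, spec.ancestor_length))
        )
        truth.labels[sid] = "decoy"
    return records, truth


def simulate_neutral_alignment(n: int, theta: float, seed: int = 0) -> Alignment:
    """Binary alignment from a neutral Kingman coalescent with infinite-sites
    mutation at rate ``theta / 2`` per unit branch length.

    With no mutations the alignment is a single monomorphic column.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)

    active: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    branches: list[tuple[frozenset[int], float]] = []
    while len(active) > 1:
        k = len(active)
        t = rng.exponential(2.0 / (k * (k - 1)))
        active = [(leaves, length + t) for leaves, length in active]
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        i, j = min(i, j), max(i, j)
        (la, ta_), (lb, tb_) = active[i], active[j]
        branches.append((la, ta_))
        branches.append((lb, tb_))
        active = [x for idx, x in enumerate(active) if idx not in (i, j)]
        active.append((la | lb, 0.0))

    columns: list[frozenset[int]] = []
    for leaves, length in branches:
        n_mut = int(rng.poisson(theta / 2.0 * length))
        columns.extend([leaves] * n_mut)
    if not columns:
        rows = ["0"] * n
    else:
        rows = [
            "".join("1" if i in carriers else "0" for carriers in columns)
            for i in range(n)
        ]
    return Alignment.from_records(
        [SequenceRecord(id=f"s{i + 1}", residues=row) for i, row in enumerate(rows)]
    )


# ---------------------------------------------------------------------------
# pipeline fixture
# ---------------------------------------------------------------------------

_REASON_CYCLE = (
    "evalue",
    "no_rbbh",
    "coverage",
    "inconsistent",
    "structure",
    "no_paralog_support",
)


def _hit(q: str, s: str, evalue: float, bitscore: float, qcov: float) -> HitRecord:
    return HitRecord(
        query_id=q,
        subject_id=s,
        percent_identity=90.0,
        alignment_length=100,
        mismatches=10,
        gap_opens=0,
        q_start=1,
        q_end=100,
        s_start=1,
        s_end=100,
        evalue=evalue,
        bitscore=bitscore,
        query_coverage=qcov,
    )


def simulate_pipeline_fixture(
    n_true: int, n_decoys: int, seed: int = 0
) -> tuple[PipelineInputs, PlantedTruth]:
    """Hit tables and annotations with a designed outcome for every protein.

    True proteins survive all five stages.  Decoys are assigned a failing
    stage round-robin over the six rejection reasons; failures at the
    coverage, transmembrane and stage-5 gates are planted exactly on the
    printed thresholds, so they exercise the strictness of each inequality.
    """
    if n_true < 0 or n_decoys < 0:
        raise ValueError("counts must be >= 0")
    truth = PlantedTruth()
    tox_f: list[HitRecord] = []
    tox_r: list[HitRecord] = []
    full_f: list[HitRecord] = []
    full_r: list[HitRecord] = []
    cnid_f: list[HitRecord] = []
    cnid_r: list[HitRecord] = []
    selfg: list[HitRecord] = []
    annotations: dict[str, AnnotationRecord] = {}

    proteins = [(f"tox{i + 1:03d}", None) for i in range(n_true)] + [
        (f"dec{i + 1:03d}", _REASON_CYCLE[i % len(_REASON_CYCLE)])
        for i in range(n_decoys)
    ]

    for idx, (pid, reason) in enumerate(proteins):
        truth.failing[pid] = reason
        truth.labels[pid] = "true" if reason is None else "decoy"
        t_sub, f_sub, nt_sub, c_sub, g_sub = (
            f"T_{pid}",
            f"F_{pid}",
            f"NT_{pid}",
            f"C_{pid}",
            f"G_{pid}",
        )

        # --- toxin database (stages 0 and 1)
        if reason == "evalue":
            tox_f.append(_hit(pid, t_sub, 1e-4, 50.0, 0.9))
            continue  # nothing else needed; fails stage 0
        cov1 = 0.70 if reason == "coverage" else 0.90  # boundary fails strict '>'
        tox_f.append(_hit(pid, t_sub, 1e-40, 200.0, cov1))
        if reason == "no_rbbh":
            tox_r.append(_hit(t_sub, "somewhere_else", 1e-50, 300.0, 0.9))
        else:
            tox_r.append(_hit(t_sub, pid, 1e-40, 200.0, 0.9))
        if reason == "coverage" or reason == "no_rbbh":
            continue

        # --- full + taxon databases (stage 2), annotated subjects (stage 3)
        full_f.append(_hit(pid, f_sub, 1e-30, 300.0, 0.9))
        full_r.append(_hit(f_sub, pid, 1e-30, 300.0, 0.9))
        nt_bits = 350.0 if reason == "inconsistent" else 250.0
        full_f.append(_hit(pid, nt_sub, 1e-25, nt_bits, 0.9))
        cnid_f.append(_hit(pid, c_sub, 1e-30, 300.0, 0.9))
        cnid_r.append(_hit(c_sub, pid, 1e-30, 300.0, 0.9))
        annotations[f_sub] = AnnotationRecord(protein_id=f_sub, is_toxin_subject=True)
        annotations[nt_sub] = AnnotationRecord(protein_id=nt_sub, is_toxin_subject=False)
        if reason == "inconsistent":
            annotations[pid] = AnnotationRecord(protein_id=pid)
            continue

        # --- structure (stage 4); tm_count == 2 sits on the boundary
        annotations[pid] = AnnotationRecord(
            protein_id=pid, tm_count=2 if reason == "structure" else 0
        )
        if reason == "structure":
            continue

        # --- own-genome support (stage 5)
        if reason == "no_paralog_support":
            if idx % 2 == 0:  # boundary coverage
                selfg.append(_hit(pid, g_sub, 1e-30, 200.0, 0.75))
            else:  # boundary e-value
                selfg.append(_hit(pid, g_sub, 1e-20, 200.0, 0.90))
            continue
        selfg.append(_hit(pid, pid, 0.0, 400.0, 1.0))
        selfg.append(_hit(pid, g_sub, 1e-30, 200.0, 0.90))

    inputs = PipelineInputs(
        hits_toxdb=tox_f,
        hits_toxdb_rev=tox_r,
        hits_fulldb=full_f,
        hits_fulldb_rev=full_r,
        hits_cniddb=cnid_f,
        hits_cniddb_rev=cnid_r,
        hits_selfgenome=selfg,
        annotations=annotations,
    )

    counts = {r: 0 for r in _REASON_CYCLE}
    for _, reason in proteins:
        if reason is not None:
            counts[reason] += 1
    n_all = n_true + n_decoys
    s0 = n_all - counts["evalue"]
    s1 = s0 - counts["no_rbbh"] - counts["coverage"]
    s3 = s1 - counts["inconsistent"]
    s4 = s3 - counts["structure"]
    truth.expected_stage_counts = [
        ("stage0_evalue", n_all, s0),
        ("stage1_toxdb_rbbh", s0, s1),
        ("stage2_dual_db", s1, s1),
        ("stage3_consistency", s1, s3),
        ("stage4_structure", s3, s4),
        ("stage5_genome_support", s4, n_true),
    ]
    return inputs, truth


def simulate_peptide_observations(
    proteins: list[SequenceRecord],
    detectable_ids: set[str],
    peptides_per_protein: int = 3,
    mismatch_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], PlantedTruth]:
    """Observed-peptide lists supporting exactly the chosen proteins.

    Detectable proteins contribute ``peptides_per_protein`` distinct tryptic
    peptides (length >= 7, up to one missed cleavage) with mismatches
    injected at the stated per-residue rate; every other protein receives at
    most one peptide.  The recovery guarantee assumes the proteins are
    mutually dissimilar.
    """
    ids = {p.id for p in proteins}
    if not detectable_ids <= ids:
        raise ValueError("detectable_ids must be a subset of the protein ids")
    rng = np.random.default_rng(seed)
    observed: list[str] = []
    truth = PlantedTruth(detectable=set(detectable_ids))
    for prot in sorted(proteins, key=lambda p: p.id):
        candidates = []
        for pep in tryptic_digest(prot.residues, max_missed=1):
            if len(pep) >= 7 and pep not in candidates:
                candidates.append(pep)
        if prot.id in detectable_ids:
            if len(candidates) < max(peptides_per_protein, 2):
                raise ValueError(
                    f"protein {prot.id!r} lacks enough long tryptic peptides"
                )
            chosen = rng.choice(len(candidates), size=peptides_per_protein, replace=False)
            for c in sorted(int(x) for x in chosen):
                pep = candidates[c]
                if mismatch_rate > 0:
                    pep = _mutate(rng, pep, mismatch_rate)
                observed.append(pep)
        elif candidates:
            observed.append(candidates[0])
    return observed, truth
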