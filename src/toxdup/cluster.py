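"""Iterative HMM-HMM duplication clustering and relationship trees.

Every input sequence starts as its own single-sequence profile HMM.  Each
iteration scores all pairs, converts scores to E-values against a Gumbel
null refreshed from shuffled-HMM decoys (``N`` = current number of HMMs),
and merges the lowest-E pair while ``E < cutoff`` (strict).  Merged members
are realigned by weaving their alignments along the winning HMM-HMM path
and the group HMM is rebuilt.  The final groups are placed on a UPGMA
relationship tree built from the initial all-vs-all E-values.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .compare import (
    CalibrationParams,
    PairAlignment,
    align_hmms,
    fit_evd,
    score_hmms,
    score_to_evalue,
)
from .formats import GAP, PROTEIN_ALPHABET, Alignment, SequenceRecord, TreeNode
from .hmm import ProfileHMM, build_profile_hmm

__all__ = [
    "DuplicationGroup",
    "GroupingResult",
    "cluster_sequences",
    "merge_alignments",
    "upgma",
    "build_group_tree",
    "duplication_report",
]

_E_FLOOR = 1e-300


@dataclass
class DuplicationGroup:
    group_id: str
    member_ids: tuple[str, ...]
    alignment: Alignment
    hmm: ProfileHMM

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class GroupingResult:
    """Partition of the input into duplication groups and singlets."""

    groups: list[DuplicationGroup]  # >= 2 members each
    singlets: list[DuplicationGroup]  # exactly 1 member each
    tree: TreeNode
    cutoff: float
    merge_log: list[tuple[int, tuple[str, ...], float]]
    pair_evalues: dict[frozenset[str], float] = field(default_factory=dict)

    def all_groups(self) -> list[DuplicationGroup]:
        return self.groups + self.singlets

    def membership(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for g in self.all_groups():
            for m in g.member_ids:
                out[m] = g.group_id
        return out


# ---------------------------------------------------------------------------
# alignment merging
# ---------------------------------------------------------------------------

def merge_alignments(
    aln_a: Alignment,
    aln_b: Alignment,
    hmm_a: ProfileHMM,
    hmm_b: ProfileHMM,
    pair: PairAlignment,
) -> Alignment:
    """Weave two group alignments together along an HMM-HMM path.

    MM steps pair the two groups' match columns; gap steps and any columns
    outside the local alignment window are emitted against gaps.  Rows are
    returned sorted by sequence id.
    """
    if pair.is_empty:
        raise ValueError("cannot merge along an empty alignment")
    col_a = hmm_a.match_columns
    col_b = hmm_b.match_columns
    plan: list[tuple[int, int]] = []  # (column of A or -1, column of B or -1)
    ca = cb = 0

    def emit_a(upto: int) -> None:
        nonlocal ca
        while ca <= upto:
            plan.append((ca, -1))
            ca += 1

    def emit_b(upto: int) -> None:
        nonlocal cb
        while cb <= upto:
            plan.append((-1, cb))
            cb += 1

    for state, i, j in pair.path:
        if state == "MM":
            emit_a(col_a[i - 1] - 1)
            emit_b(col_b[j - 1] - 1)
            plan.append((col_a[i - 1], col_b[j - 1]))
            ca, cb = col_a[i - 1] + 1, col_b[j - 1] + 1
        elif state in ("MI", "DG"):
            emit_a(col_a[i - 1])
        else:  # IM, GD
            emit_b(col_b[j - 1])
    emit_a(aln_a.n_cols - 1)
    emit_b(aln_b.n_cols - 1)

    rows: list[SequenceRecord] = []
    for rec in aln_a.members:
        residues = "".join(rec.residues[ja] if ja >= 0 else GAP for ja, _ in plan)
        rows.append(SequenceRecord(id=rec.id, residues=residues, description=rec.description))
    for rec in aln_b.members:
        residues = "".join(rec.residues[jb] if jb >= 0 else GAP for _, jb in plan)
        rows.append(SequenceRecord(id=rec.id, residues=residues, description=rec.description))
    rows.sort(key=lambda r: r.id)
    return Alignment.from_records(rows)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _shuffle_seed(base_seed: int, key: str, idx: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([base_seed, zlib.crc32(key.encode()), idx])


class _ClusterState:
    def __init__(self, seed: int, pseudocount_weight: float, background, alphabet: str):
        self.seed = seed
        self.pcw = pseudocount_weight
        self.background = background
        self.alphabet = alphabet
        self.groups: dict[str, tuple[tuple[str, ...], Alignment, ProfileHMM]] = {}
        self.scores: dict[frozenset[str], float] = {}
        self.partners: list[ProfileHMM] = []  # neutral random-background HMMs
        self.decoy_scores: dict[str, list[float]] = {}
        self.n_shuffles = 0

    def build_hmm(self, alignment: Alignment, name: str) -> ProfileHMM:
        return build_profile_hmm(
            alignment,
            pseudocount_weight=self.pcw,
            background=self.background,
            alphabet=self.alphabet,
            name=name,
        )

    def add_group(self, key: str, members: tuple[str, ...], alignment: Alignment,
                  hmm: ProfileHMM) -> None:
        self.groups[key] = (members, alignment, hmm)
        for other in self.groups:
            if other != key:
                pair = frozenset((key, other))
                self.scores[pair] = score_hmms(hmm, self.groups[other][2])

    def drop_group(self, key: str) -> None:
        del self.groups[key]
        self.decoy_scores.pop(key, None)
        for pair in [p for p in self.scores if key in p]:
            del self.scores[pair]

    def make_partners(self, n_partners: int, lengths: list[int]) -> None:
        """Neutral calibration partners: single random sequences drawn from
        the background, lengths mirroring the input length multiset."""
        alphabet = self.alphabet
        bg = self.background
        if bg is None:
            probs = np.full(len(alphabet), 1.0 / len(alphabet))
        else:
            probs = np.asarray(bg, dtype=float)
            probs = probs / probs.sum()
        lengths = sorted(lengths)
        self.partners = []
        for idx in range(n_partners):
            length = lengths[idx % len(lengths)]
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, 0x9E3779B9, idx])
            )
            residues = "".join(
                alphabet[i] for i in rng.choice(len(alphabet), size=length, p=probs)
            )
            aln = Alignment.from_records(
                [SequenceRecord(id=f"partner{idx}", residues=residues)]
            )
            self.partners.append(self.build_hmm(aln, f"partner{idx}"))

    def refresh_decoys(self, min_scores: int) -> None:
        """Decoy scores per group: shuffled copies of the group HMM scored
        against the neutral partner HMMs."""
        from .hmm import shuffle_hmm

        n_partners = max(len(self.partners), 1)
        m = max(
            1, -(-min_scores // (len(self.groups) * n_partners))
        )  # ceil division
        if m != self.n_shuffles:
            self.n_shuffles = m
            self.decoy_scores = {}
        for key in sorted(self.groups):
            if key not in self.decoy_scores:
                hmm = self.groups[key][2]
                scores: list[float] = []
                for idx in range(m):
                    ss = _shuffle_seed(self.seed, key, idx)
                    decoy = shuffle_hmm(hmm, int(np.random.default_rng(ss).integers(2**31)))
                    scores.extend(score_hmms(decoy, p) for p in self.partners)
                self.decoy_scores[key] = scores

    def calibration(self, truncate_upper: float = 0.0) -> CalibrationParams:
        pool = [s for scores in self.decoy_scores.values() for s in scores]
        return fit_evd(
            pool, n_comparisons=len(self.groups), truncate_upper=truncate_upper
        )

    def evalues(self, params: CalibrationParams) -> dict[frozenset[str], float]:
        return {
            pair: score_to_evalue(score, params)[1]
            for pair, score in self.scores.items()
        }


def _select_merge(
    evalues: dict[frozenset[str], float], cutoff: float
) -> tuple[frozenset[str], float] | None:
    """Best-first merge choice: strictly below cutoff, lowest E, ties broken
    lexicographically by the sorted key pair."""
    best: tuple[float, tuple[str, str]] | None = None
    for pair, e in evalues.items():
        if not e < cutoff:
            continue
        item = (e, tuple(sorted(pair)))
        if best is None or item < best:
            best = item
    if best is None:
        return None
    return frozenset(best[1]), best[0]


def cluster_sequences(
    seqs: list[SequenceRecord],
    cutoff: float = 1e-20,
    seed: int = 0,
    pseudocount_weight: float = 1.0,
    background=None,
    alphabet: str = PROTEIN_ALPHABET,
    single_pass: bool = False,
    min_decoy_scores: int = 200,
    n_partners: int = 8,
) -> GroupingResult:
    """Cluster sequences into duplication groups by iterative HMM merging.

    Calibration: each group HMM is shuffled (seeded) and scored against
    ``n_partners`` neutral HMMs built from background-sampled random
    sequences; a Gumbel is refitted to the pooled decoy scores every
    iteration with ``N`` = the current number of HMMs.  ``min_decoy_scores``
    sets the pool size each refit must reach.  ``single_pass=True`` clusters
    from the initial all-vs-all E-value matrix alone (minimum linkage),
    without rebuilding group HMMs after merges.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    singles = {
        s.id: Alignment.from_records(
            [SequenceRecord(id=s.id, residues=s.residues.replace(GAP, ""),
                            description=s.description)]
        )
        for s in seqs
    }

    state = _ClusterState(seed, pseudocount_weight, background, alphabet)
    for sid in sorted(singles):
        aln = singles[sid]
        state.add_group(sid, (sid,), aln, state.build_hmm(aln, sid))
    state.make_partners(
        n_partners, [len(a.members[0].residues) for a in singles.values()]
    )

    merge_log: list[tuple[int, tuple[str, ...], float]] = []
    initial_evalues: dict[frozenset[str], float] = {}

    if len(state.groups) == 1:
        return _finalise(state, cutoff, merge_log, initial_evalues)

    iteration = 0
    while len(state.groups) > 1:
        iteration += 1
        state.refresh_decoys(min_decoy_scores)
        params = state.calibration()
        evalues = state.evalues(params)
        if iteration == 1:
            initial_evalues = dict(evalues)
            if single_pass:
                return _single_pass(
                    state, initial_evalues, cutoff, merge_log
                )
        chosen = _select_merge(evalues, cutoff)
        if chosen is None:
            break
        pair, e = chosen
        key_a, key_b = sorted(pair)
        members_a, aln_a, hmm_a = state.groups[key_a]
        members_b, aln_b, hmm_b = state.groups[key_b]
        path = align_hmms(hmm_a, hmm_b)
        merged_aln = merge_alignments(aln_a, aln_b, hmm_a, hmm_b, path)
        merged_members = tuple(sorted(members_a + members_b))
        state.drop_group(key_a)
        state.drop_group(key_b)
        new_key = min(merged_members)
        state.add_group(
            new_key, merged_members, merged_aln, state.build_hmm(merged_aln, new_key)
        )
        merge_log.append((iteration, merged_members, e))

    return _finalise(state, cutoff, merge_log, initial_evalues)


def _single_pass(
    state: _ClusterState,
    evalues: dict[frozenset[str], float],
    cutoff: float,
    merge_log: list,
) -> GroupingResult:
    """Minimum-linkage agglomeration on the initial E-value matrix."""
    members: dict[str, tuple[str, ...]] = {
        k: v[0] for k, v in state.groups.items()
    }
    linkage = {
        frozenset(p): e for p, e in evalues.items()
    }
    iteration = 0
    while len(members) > 1:
        iteration += 1
        chosen = _select_merge(linkage, cutoff)
        if chosen is None:
            break
        pair, e = chosen
        key_a, key_b = sorted(pair)
        merged = tuple(sorted(members[key_a] + members[key_b]))
        new_key = min(merged)
        for d in [linkage]:
            updates = {}
            for other in members:
                if other in (key_a, key_b):
                    continue
                candidates = [
                    d.get(frozenset((key_a, other)), math.inf),
                    d.get(frozenset((key_b, other)), math.inf),
                ]
                updates[frozenset((new_key, other))] = min(candidates)
            for p in [p for p in d if key_a in p or key_b in p]:
                del d[p]
            d.update(updates)
        del members[key_a]
        del members[key_b]
        members[new_key] = merged
        merge_log.append((iteration, merged, e))

    # rebuild group alignments for merged sets by progressive pairwise merges
    result_groups: dict[str, tuple[tuple[str, ...], Alignment, ProfileHMM]] = {}
    for key, mids in members.items():
        if len(mids) == 1:
            result_groups[key] = state.groups[key]
        else:
            aln, hmm = None, None
            for mid in mids:
                m_members, m_aln, m_hmm = state.groups[mid]
                if aln is None:
                    aln, hmm = m_aln, m_hmm
                else:
                    path = align_hmms(hmm, m_hmm)
                    if path.is_empty:
                        raise ValueError(
                            f"cannot align members of single-pass group {key!r}"
                        )
                    aln = merge_alignments(aln, m_aln, hmm, m_hmm, path)
                    hmm = state.build_hmm(aln, key)
            result_groups[key] = (mids, aln, hmm)
    state.groups = result_groups
    return _finalise(state, cutoff, merge_log, evalues)


def _finalise(
    state: _ClusterState,
    cutoff: float,
    merge_log: list,
    initial_evalues: dict[frozenset[str], float],
) -> GroupingResult:
    ordered = sorted(state.groups.values(), key=lambda g: g[0][0])
    groups: list[DuplicationGroup] = []
    singlets: list[DuplicationGroup] = []
    for idx, (members, aln, hmm) in enumerate(ordered, start=1):
        group = DuplicationGroup(
            group_id=f"g{idx}", member_ids=members, alignment=aln, hmm=hmm
        )
        (groups if group.n_members >= 2 else singlets).append(group)
    result = GroupingResult(
        groups=groups,
        singlets=singlets,
        tree=TreeNode(),
        cutoff=cutoff,
        merge_log=merge_log,
        pair_evalues=initial_evalues,
    )
    result.tree = build_group_tree(result, initial_evalues)
    return result


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def evalue_to_distance(e: float) -> float:
    """Transform an E-value into a UPGMA distance: ``300 - (-log10(max(E, 1e-300)))``."""
    return 300.0 - (-math.log10(max(e, _E_FLOOR)))


def upgma(labels: list[str], dist: dict[frozenset[str], float]) -> TreeNode:
    """Unweighted pair-group (average linkage) tree; heights are d/2.

    Tie-breaking is lexicographic on the (smallest-leaf, smallest-leaf)
    label pair, so the topology is deterministic.
    """
    if not labels:
        raise ValueError("no leaves")
    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in labels}
    heights: dict[str, float] = {lab: 0.0 for lab in labels}
    sizes: dict[str, int] = {lab: 1 for lab in labels}
    d = {frozenset(p): v for p, v in dist.items()}
    active = sorted(labels)
    while len(active) > 1:
        best: tuple[float, tuple[str, str]] | None = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                pair = (active[i], active[j])
                v = d[frozenset(pair)]
                item = (v, pair)
                if best is None or item < best:
                    best = item
        v, (ka, kb) = best
        height = v / 2.0
        na, nb = nodes[ka], nodes[kb]
        na.length = max(height - heights[ka], 0.0)
        nb.length = max(height - heights[kb], 0.0)
        parent = TreeNode(children=[na, nb])
        new_key = min(ka, kb)
        for other in active:
            if other in (ka, kb):
                continue
            va = d[frozenset((ka, other))]
            vb = d[frozenset((kb, other))]
            merged = (va * sizes[ka] + vb * sizes[kb]) / (sizes[ka] + sizes[kb])
            d[frozenset((new_key, other))] = merged
        for p in [p for p in d if ka in p or kb in p]:
            if new_key not in p or (ka in p and kb in p):
                del d[p]
        active = sorted(set(active) - {ka, kb} | {new_key})
        nodes.pop(ka, None)
        nodes.pop(kb, None)
        nodes[new_key] = parent
        heights[new_key] = height
        sizes[new_key] = sizes.pop(ka) + sizes.pop(kb)
    return nodes[active[0]]


def build_group_tree(
    result: GroupingResult, pair_evalues: dict[frozenset[str], float]
) -> TreeNode:
    """UPGMA tree over groups and singlets.

    Between-group distance: minimum member-pair E-value, transformed with
    :func:`evalue_to_distance`.
    """
    all_groups = result.all_groups()
    if len(all_groups) == 1:
        return TreeNode(label=all_groups[0].group_id)
    dist: dict[frozenset[str], float] = {}
    for i in range(len(all_groups)):
        for j in range(i + 1, len(all_groups)):
            ga, gb = all_groups[i], all_groups[j]
            e_min = min(
                pair_evalues.get(frozenset((ma, mb)), 1.0)
                for ma in ga.member_ids
                for mb in gb.member_ids
            )
            dist[frozenset((ga.group_id, gb.group_id))] = evalue_to_distance(e_min)
    return upgma([g.group_id for g in all_groups], dist)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def duplication_report(
    result: GroupingResult, detected_ids: set[str] | None = None
) -> dict:
    """Headline duplication statistics for a grouping.

    ``fraction_pct`` is members-of-multi-groups over all sequences, rounded
    to a whole percent.  With ``detected_ids``, adds the detected fraction
    and the share of detected sequences that sit inside duplication groups.
    """
    n_in_groups = sum(g.n_members for g in result.groups)
    n_singlets = len(result.singlets)
    n_total = n_in_groups + n_singlets
    report = {
        "n_total": n_total,
        "n_groups": len(result.groups),
        "n_in_groups": n_in_groups,
        "n_singlets": n_singlets,
        "fraction_pct": int(round(100.0 * n_in_groups / n_total)) if n_total else 0,
    }
    if detected_ids is not None:
        membership = result.membership()
        group_ids = {g.group_id for g in result.groups}
        n_detected = len(detected_ids)
        n_detected_in_groups = sum(
            1 for sid in detected_ids if membership.get(sid) in group_ids
        )
        report["n_detected"] = n_detected
        report["detected_pct"] = (
            int(round(100.0 * n_detected / n_total)) if n_total else 0
        )
        report["detected_in_groups"] = n_detected_in_groups
        report["detected_in_groups_pct"] = (
            int(round(100.0 * n_detected_in_groups / n_detected)) if n_detected else 0
        )
    return report
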