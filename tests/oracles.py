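"""Independent reference implementations used as test oracles.

Everything here is deliberately written by brute force / direct formula
evaluation, independent of the library's own algorithms.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from toxdup.formats import Alignment, SequenceRecord
from toxdup.hmm import T_DD, T_DM, T_II, T_IM, T_MD, T_MI, T_MM, build_profile_hmm
from toxdup.compare import column_score_matrix

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_hmm(rng: np.random.Generator, L: int, n_seqs: int = 2, **kwargs):
    rows = [
        "".join(AA[i] for i in rng.integers(0, 20, L)) for _ in range(n_seqs)
    ]
    aln = Alignment.from_records(
        [SequenceRecord(id=f"s{i}", residues=r) for i, r in enumerate(rows)]
    )
    return build_profile_hmm(aln, **kwargs)


def brute_force_best_local_score(a, b) -> float:
    """Exhaustive enumeration of all legal local pair-state paths.

    Paths start and end in MM; between consecutive MM steps runs a
    homogeneous stretch of one gap state (MI, IM, DG or GD).  The best
    positive path score is returned, 0.0 if none is positive.
    """
    La, Lb = a.L, b.L
    S = column_score_matrix(a, b)
    with np.errstate(divide="ignore"):
        ta, tb = np.log2(a.transitions), np.log2(b.transitions)
    best = 0.0

    def extend(state: str, i: int, j: int, score: float) -> None:
        nonlocal best
        if state == "MM":
            best = max(best, score)
            if i < La and j < Lb:
                extend("MM", i + 1, j + 1, score + ta[i, T_MM] + tb[j, T_MM] + S[i, j])
            if i < La:
                extend("MI", i + 1, j, score + ta[i, T_MM] + tb[j, T_MI])
                extend("DG", i + 1, j, score + ta[i, T_MD])
            if j < Lb:
                extend("IM", i, j + 1, score + ta[i, T_MI] + tb[j, T_MM])
                extend("GD", i, j + 1, score + tb[j, T_MD])
        elif state == "MI":
            if i < La and j < Lb:
                extend("MM", i + 1, j + 1, score + ta[i, T_MM] + tb[j, T_IM] + S[i, j])
            if i < La:
                extend("MI", i + 1, j, score + ta[i, T_MM] + tb[j, T_II])
        elif state == "IM":
            if i < La and j < Lb:
                extend("MM", i + 1, j + 1, score + ta[i, T_IM] + tb[j, T_MM] + S[i, j])
            if j < Lb:
                extend("IM", i, j + 1, score + ta[i, T_II] + tb[j, T_MM])
        elif state == "DG":
            if i < La and j < Lb:
                extend("MM", i + 1, j + 1, score + ta[i, T_DM] + tb[j, T_MM] + S[i, j])
            if i < La:
                extend("DG", i + 1, j, score + ta[i, T_DD])
        else:  # GD
            if i < La and j < Lb:
                extend("MM", i + 1, j + 1, score + ta[i, T_MM] + tb[j, T_DM] + S[i, j])
            if j < Lb:
                extend("GD", i, j + 1, score + tb[j, T_DD])

    for i in range(La):
        for j in range(Lb):
            extend("MM", i + 1, j + 1, S[i, j])
    return best


def direct_tajima_d(rows: list[str]) -> dict:
    """Direct-formula Tajima computation on gap/ambiguity-free columns,
    using a naive all-pairs difference count."""
    n = len(rows)
    skip = set("-.XNxn?*")
    cols = [
        [row[j] for row in rows]
        for j in range(len(rows[0]))
        if not any(row[j] in skip for row in rows)
    ]
    S = sum(1 for col in cols if len(set(col)) > 1)
    total = 0
    pairs = list(combinations(range(n), 2))
    for i, k in pairs:
        total += sum(1 for col in cols if col[i] != col[k])
    pi = total / len(pairs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if S > 0 and var > 0:
        D = (pi - S / a1) / math.sqrt(var)
    else:
        D = float("nan")
    return {"S": S, "pi": pi, "a1": a1, "D": D}


def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index from the pair-counting contingency table."""
    assert len(labels_a) == len(labels_b)
    n = len(labels_a)
    cells: dict[tuple, int] = {}
    row: dict = {}
    col: dict = {}
    for a, b in zip(labels_a, labels_b):
        cells[(a, b)] = cells.get((a, b), 0) + 1
        row[a] = row.get(a, 0) + 1
        col[b] = col.get(b, 0) + 1
    comb2 = lambda x: x * (x - 1) / 2.0  # noqa: E731
    sum_cells = sum(comb2(v) for v in cells.values())
    sum_row = sum(comb2(v) for v in row.values())
    sum_col = sum(comb2(v) for v in col.values())
    expected = sum_row * sum_col / comb2(n)
    max_index = (sum_row + sum_col) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)


def rbbh_double_loop(hits_ab, hits_ba) -> set[tuple[str, str]]:
    """Exhaustive double-loop strict RBBH oracle."""

    def rank1(hits, q):
        rows = [h for h in hits if h.query_id == q]
        if not rows:
            return None
        return min(rows, key=lambda h: (h.evalue, -h.bitscore, h.subject_id)).subject_id

    out = set()
    for h in hits_ab:
        a, b = h.query_id, h.subject_id
        if rank1(hits_ab, a) == b and rank1(hits_ba, b) == a:
            out.add((a, b))
    return out


def topk_rbbh_double_loop(hits_ab, hits_ba, k) -> set[tuple[str, str]]:
    def topk(hits, q):
        rows = [h for h in hits if h.query_id == q]
        rows.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        return [h.subject_id for h in rows[:k]]

    out = set()
    for h in hits_ab:
        a, b = h.query_id, h.subject_id
        if b in topk(hits_ab, a) and a in topk(hits_ba, b):
            out.add((a, b))
    return out
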