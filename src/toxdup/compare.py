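"""Pairwise profile-HMM comparison and E-value calibration.

Two HMMs are compared by a local dynamic program over five pair states —
MM, MI, IM, DG, GD — in the style of HMM-HMM alignment tools: MM cells add
the log2 co-emission score of the two match columns, every step adds the
log2 product of the transition probabilities it traverses in each model,
and the MM recurrence is floored at zero so the best local segment wins.

Raw bit scores are converted to P-values through a Gumbel (type-I extreme
value) distribution fitted to decoy scores, and to E-values as
``E = P * n_comparisons``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .hmm import T_DD, T_DM, T_II, T_IM, T_MD, T_MI, T_MM, ProfileHMM

__all__ = [
    "PairAlignment",
    "CalibrationParams",
    "ComparisonResult",
    "column_score",
    "column_score_matrix",
    "align_hmms",
    "score_hmms",
    "fit_evd",
    "score_to_evalue",
    "compare_hmms",
]

_NEG = float("-inf")


@dataclass(frozen=True)
class PairAlignment:
    """A local HMM-HMM alignment path.

    ``path`` is an ordered list of ``(state, i, j)`` triples with 1-based
    match-state coordinates; MM consumes a column of both models, MI/DG
    consume only the first model's column, IM/GD only the second's.
    """

    path: tuple[tuple[str, int, int], ...]
    score_bits: float

    @property
    def is_empty(self) -> bool:
        return not self.path

    @property
    def start(self) -> tuple[int, int] | None:
        return self.path[0][1:] if self.path else None

    @property
    def end(self) -> tuple[int, int] | None:
        return self.path[-1][1:] if self.path else None


@dataclass(frozen=True)
class CalibrationParams:
    """Gumbel parameters for score->P conversion plus the comparison count."""

    lam: float
    mu: float
    n_comparisons: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Gumbel scale lambda must be positive")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")


@dataclass(frozen=True)
class ComparisonResult:
    hmm_a: str
    hmm_b: str
    score_bits: float
    p_value: float
    e_value: float


def column_score(q: np.ndarray, p: np.ndarray, f: np.ndarray) -> float:
    """log2 co-emission score of two emission rows against background ``f``.

    Returns ``log2(sum_a q(a) * p(a) / f(a))``; ``-inf`` when the supports
    are disjoint.
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    if q.shape != p.shape or q.shape != f.shape:
        raise ValueError("emission rows and background must share one alphabet")
    if np.any(f <= 0):
        raise ValueError("background must be strictly positive")
    s = float(np.dot(q, p / f))
    return math.log2(s) if s > 0 else _NEG


def column_score_matrix(a: ProfileHMM, b: ProfileHMM) -> np.ndarray:
    """All-pairs column scores, shape (a.L, b.L)."""
    inner = a.match_emissions @ (b.match_emissions / a.background).T
    with np.errstate(divide="ignore"):
        return np.log2(inner)


def _check_compatible(a: ProfileHMM, b: ProfileHMM) -> None:
    if a.alphabet != b.alphabet:
        raise ValueError(f"alphabet mismatch: {a.name!r} vs {b.name!r}")
    if not np.allclose(a.background, b.background):
        raise ValueError("HMMs were built against different backgrounds")


def _log_transitions(h: ProfileHMM) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(h.transitions)


def align_hmms(a: ProfileHMM, b: ProfileHMM) -> PairAlignment:
    """Optimal local pair alignment of two HMMs with full traceback.

    Returns the empty alignment (score 0) when no cell scores positively.
    """
    _check_compatible(a, b)
    La, Lb = a.L, b.L
    S = column_score_matrix(a, b)
    ta, tb = _log_transitions(a), _log_transitions(b)

    MM = np.full((La + 1, Lb + 1), _NEG)
    MI = np.full((La + 1, Lb + 1), _NEG)
    IM = np.full((La + 1, Lb + 1), _NEG)
    DG = np.full((La + 1, Lb + 1), _NEG)
    GD = np.full((La + 1, Lb + 1), _NEG)
    # pointers: MM cell came from 0=restart 1=MM 2=MI 3=IM 4=DG 5=GD;
    # gap-state cells: 1=from MM, 0=extension
    pmm = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    pmi = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    pim = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    pdg = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    pgd = np.zeros((La + 1, Lb + 1), dtype=np.int8)

    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            cands = (
                0.0,
                MM[i - 1, j - 1] + ta[i - 1, T_MM] + tb[j - 1, T_MM],
                MI[i - 1, j - 1] + ta[i - 1, T_MM] + tb[j - 1, T_IM],
                IM[i - 1, j - 1] + ta[i - 1, T_IM] + tb[j - 1, T_MM],
                DG[i - 1, j - 1] + ta[i - 1, T_DM] + tb[j - 1, T_MM],
                GD[i - 1, j - 1] + ta[i - 1, T_MM] + tb[j - 1, T_DM],
            )
            best = max(range(6), key=lambda k: cands[k])
            MM[i, j] = S[i - 1, j - 1] + cands[best]
            pmm[i, j] = best

            v_open = MM[i - 1, j] + ta[i - 1, T_MM] + tb[j, T_MI]
            v_ext = MI[i - 1, j] + ta[i - 1, T_MM] + tb[j, T_II]
            if v_open >= v_ext:
                MI[i, j], pmi[i, j] = v_open, 1
            else:
                MI[i, j], pmi[i, j] = v_ext, 0

            v_open = MM[i - 1, j] + ta[i - 1, T_MD]
            v_ext = DG[i - 1, j] + ta[i - 1, T_DD]
            if v_open >= v_ext:
                DG[i, j], pdg[i, j] = v_open, 1
            else:
                DG[i, j], pdg[i, j] = v_ext, 0

            v_open = MM[i, j - 1] + ta[i, T_MI] + tb[j - 1, T_MM]
            v_ext = IM[i, j - 1] + ta[i, T_II] + tb[j - 1, T_MM]
            if v_open >= v_ext:
                IM[i, j], pim[i, j] = v_open, 1
            else:
                IM[i, j], pim[i, j] = v_ext, 0

            v_open = MM[i, j - 1] + tb[j - 1, T_MD]
            v_ext = GD[i, j - 1] + tb[j - 1, T_DD]
            if v_open >= v_ext:
                GD[i, j], pgd[i, j] = v_open, 1
            else:
                GD[i, j], pgd[i, j] = v_ext, 0

    flat = np.argmax(MM)
    bi, bj = divmod(int(flat), Lb + 1)
    best_score = MM[bi, bj]
    if not best_score > 0:
        return PairAlignment(path=(), score_bits=0.0)

    # traceback
    path: list[tuple[str, int, int]] = []
    state, i, j = "MM", bi, bj
    while True:
        path.append((state, i, j))
        if state == "MM":
            came = pmm[i, j]
            if came == 0:
                break
            state = ("MM", "MM", "MI", "IM", "DG", "GD")[came]
            i, j = i - 1, j - 1
        elif state == "MI":
            came = pmi[i, j]
            state = "MM" if came == 1 else "MI"
            i -= 1
        elif state == "DG":
            came = pdg[i, j]
            state = "MM" if came == 1 else "DG"
            i -= 1
        elif state == "IM":
            came = pim[i, j]
            state = "MM" if came == 1 else "IM"
            j -= 1
        else:  # GD
            came = pgd[i, j]
            state = "MM" if came == 1 else "GD"
            j -= 1
    path.reverse()
    return PairAlignment(path=tuple(path), score_bits=float(best_score))


def score_hmms(a: ProfileHMM, b: ProfileHMM) -> float:
    """Best local pair-alignment score in bits, without traceback.

    Row-vectorised version of :func:`align_hmms`; the IM/GD within-row
    recursions are solved with a prefix-max transform.  Agrees with
    ``align_hmms(a, b).score_bits`` (tested), and is symmetric in its
    arguments.
    """
    _check_compatible(a, b)
    La, Lb = a.L, b.L
    S = column_score_matrix(a, b)
    ta, tb = _log_transitions(a), _log_transitions(b)

    b_mm = tb[:, T_MM]
    neg_row = np.full(Lb + 1, _NEG)
    mm_prev = neg_row.copy()
    mi_prev = neg_row.copy()
    im_prev = neg_row.copy()
    dg_prev = neg_row.copy()
    gd_prev = neg_row.copy()
    best = 0.0

    for i in range(1, La + 1):
        a_mm, a_md = ta[i - 1, T_MM], ta[i - 1, T_MD]
        a_im, a_dm, a_dd = ta[i - 1, T_IM], ta[i - 1, T_DM], ta[i - 1, T_DD]
        # candidates into MM(i, j) use previous-row cells at j-1
        cand = np.maximum.reduce(
            [
                np.zeros(Lb),
                mm_prev[:-1] + a_mm + b_mm[:-1],
                mi_prev[:-1] + a_mm + tb[:-1, T_IM],
                im_prev[:-1] + a_im + b_mm[:-1],
                dg_prev[:-1] + a_dm + b_mm[:-1],
                gd_prev[:-1] + a_mm + tb[:-1, T_DM],
            ]
        )
        mm_row = neg_row.copy()
        mm_row[1:] = S[i - 1, :] + cand
        row_best = mm_row[1:].max()
        if row_best > best:
            best = float(row_best)

        mi_row = neg_row.copy()
        mi_row[1:] = np.maximum(
            mm_prev[1:] + a_mm + tb[1:, T_MI], mi_prev[1:] + a_mm + tb[1:, T_II]
        )
        dg_row = neg_row.copy()
        dg_row[1:] = np.maximum(mm_prev[1:] + a_md, dg_prev[1:] + a_dd)

        # IM(i, j) = max(MM(i, j-1) + a_mi' + b_mm[j-1], IM(i, j-1) + a_ii' + b_mm[j-1])
        # where a_mi'/a_ii' use node i transitions of model a.
        step = ta[i, T_II] + b_mm[:-1]  # per-j extension cost, j = 1..Lb
        csum = np.cumsum(step)
        y = mm_row[:-1] + ta[i, T_MI] + b_mm[:-1] - csum
        im_row = neg_row.copy()
        im_row[1:] = np.maximum.accumulate(y) + csum

        step_g = tb[:-1, T_DD]
        csum_g = np.cumsum(step_g)
        yg = mm_row[:-1] + tb[:-1, T_MD] - csum_g
        gd_row = neg_row.copy()
        gd_row[1:] = np.maximum.accumulate(yg) + csum_g

        mm_prev, mi_prev, im_prev, dg_prev, gd_prev = (
            mm_row,
            mi_row,
            im_row,
            dg_row,
            gd_row,
        )
    return best


def fit_evd(
    decoy_scores, n_comparisons: int = 1, truncate_upper: float = 0.0
) -> CalibrationParams:
    """Maximum-likelihood Gumbel fit to decoy scores.

    Requires at least 50 finite scores; the fit is independent of input
    order.  Raises on degenerate (constant) input.

    ``truncate_upper`` discards that fraction of the highest scores and
    maximises the correspondingly truncated likelihood.  This guards the
    null fit against contamination by genuinely related decoy pairs (e.g.
    shuffles of near-identical models), which otherwise fatten the tail.
    """
    scores = np.asarray([s for s in decoy_scores if math.isfinite(s)], dtype=float)
    if scores.size < 50:
        raise ValueError(f"insufficient decoys: {scores.size} finite scores (need >= 50)")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate fit: decoy scores are constant")
    if not 0.0 <= truncate_upper < 1.0:
        raise ValueError("truncate_upper must be in [0, 1)")
    scores = np.sort(scores)  # order independence, bit for bit

    if truncate_upper == 0.0:
        loc, scale = stats.gumbel_r.fit(scores)
    else:
        k = int(math.ceil(scores.size * (1.0 - truncate_upper)))
        kept = scores[:k]
        cut = kept[-1]
        if np.ptp(kept) == 0:
            raise ValueError("degenerate fit: kept decoy scores are constant")
        loc0, scale0 = stats.gumbel_r.fit(kept)

        def nll(params: np.ndarray) -> float:
            mu, log_beta = params
            beta = math.exp(log_beta)
            ll = stats.gumbel_r.logpdf(kept, loc=mu, scale=beta).sum()
            ll -= kept.size * stats.gumbel_r.logcdf(cut, loc=mu, scale=beta)
            return -float(ll)

        res = optimize.minimize(
            nll,
            np.array([loc0, math.log(scale0)]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        loc, scale = float(res.x[0]), math.exp(float(res.x[1]))

    if not (scale > 0 and math.isfinite(scale) and math.isfinite(loc)):
        raise ValueError("degenerate Gumbel fit")
    return CalibrationParams(lam=1.0 / scale, mu=float(loc), n_comparisons=n_comparisons)


def score_to_evalue(
    score_bits: float, params: CalibrationParams
) -> tuple[float, float]:
    """Convert a bit score to ``(p_value, e_value)`` under a Gumbel null.

    ``p = 1 - exp(-exp(-lam * (S - mu)))`` and ``E = p * n_comparisons``.
    """
    t = math.exp(-params.lam * (score_bits - params.mu))
    p = -math.expm1(-t)
    p = min(max(p, 0.0), 1.0)
    return p, p * params.n_comparisons


def compare_hmms(
    a: ProfileHMM, b: ProfileHMM, params: CalibrationParams
) -> ComparisonResult:
    """Symmetrised comparison: the scoring function is symmetric, so one
    evaluation covers both directions; the lower of the two (identical)
    E-values is returned by construction."""
    score = score_hmms(a, b)
    p, e = score_to_evalue(score, params)
    return ComparisonResult(hmm_a=a.name, hmm_b=b.name, score_bits=score, p_value=p, e_value=e)
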