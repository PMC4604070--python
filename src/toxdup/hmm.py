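"""Profile-HMM construction from multiple alignments.

A :class:`ProfileHMM` is the unit compared by the clustering engine: one
match state per alignment column with strictly more than 50 % non-gap
characters, pseudocount-smoothed emissions and Plan7-style transition
probabilities (no I<->D transitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import GAP, PROTEIN_ALPHABET, Alignment

__all__ = [
    "ProfileHMM",
    "build_profile_hmm",
    "shuffle_hmm",
    "uniform_background",
    "read_background",
    "henikoff_weights",
]

# transition columns, indexed into ProfileHMM.transitions
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)
_M_OUT = (T_MM, T_MI, T_MD)
_I_OUT = (T_IM, T_II)
_D_OUT = (T_DM, T_DD)

_NORM_TOL = 1e-9


def uniform_background(alphabet: str = PROTEIN_ALPHABET) -> np.ndarray:
    return np.full(len(alphabet), 1.0 / len(alphabet))


def read_background(path, alphabet: str = PROTEIN_ALPHABET) -> np.ndarray:
    """Read a two-column (residue, frequency) background table; renormalises."""
    freqs = np.zeros(len(alphabet))
    index = {a: i for i, a in enumerate(alphabet)}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or parts[0] not in index:
                raise ValueError(f"{path}:{lineno}: bad background row {line!r}")
            freqs[index[parts[0]]] = float(parts[1])
    if np.any(freqs <= 0):
        raise ValueError(f"{path}: background must be strictly positive for all residues")
    return freqs / freqs.sum()


@dataclass
class ProfileHMM:
    """Position-specific emission/transition model over ``L`` match states.

    ``transitions`` has shape ``(L + 1, 7)``: row ``i`` holds the outgoing
    probabilities of node ``i``'s match/insert/delete states towards node
    ``i + 1`` (node 0 is the begin node).  The three M-out, two I-out and
    two D-out entries of each row each sum to one.
    """

    name: str
    alphabet: str
    match_emissions: np.ndarray  # (L, K)
    insert_emissions: np.ndarray  # (L, K)
    transitions: np.ndarray  # (L + 1, 7)
    background: np.ndarray  # (K,)
    n_seqs: int
    match_columns: tuple[int, ...]  # alignment columns that became match states

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, tol: float = _NORM_TOL) -> None:
        if self.L < 1:
            raise ValueError("profile HMM must have at least one match state")
        if np.any(self.background <= 0):
            raise ValueError("background must be strictly positive")
        for rows, what in (
            (self.match_emissions, "match emission"),
            (self.insert_emissions, "insert emission"),
        ):
            if np.max(np.abs(rows.sum(axis=1) - 1.0)) > tol:
                raise ValueError(f"{what} rows do not sum to 1")
        for out, what in ((_M_OUT, "M"), (_I_OUT, "I"), (_D_OUT, "D")):
            sums = self.transitions[:, list(out)].sum(axis=1)
            if np.max(np.abs(sums - 1.0)) > tol:
                raise ValueError(f"{what}-state transitions do not sum to 1")


def henikoff_weights(alignment: Alignment) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff 1994), scaled to
    sum to the number of rows."""
    n = alignment.n_rows
    weights = np.zeros(n)
    for j in range(alignment.n_cols):
        col = alignment.column(j)
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, ch in enumerate(col):
            if ch != GAP:
                weights[i] += 1.0 / (r * counts[ch])
    if weights.sum() == 0:
        return np.full(n, 1.0)
    return weights * (n / weights.sum())


def build_profile_hmm(
    alignment: Alignment,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    alphabet: str = PROTEIN_ALPHABET,
    name: str | None = None,
    weighting: str = "uniform",
    transition_smoothing: float = 0.2,
) -> ProfileHMM:
    """Build a profile HMM from a multiple alignment.

    Match columns are those with strictly more than 50 % non-gap characters.
    Match emissions are ``(weighted counts + w * f(a)) / (total + w)`` with
    ``w = pseudocount_weight``; insert emissions equal the background.
    Transition probabilities come from the observed per-row state paths with
    add-constant smoothing of weight ``transition_smoothing`` (a Laplace-style
    +1 scheme, scaled down by default so that single-sequence models keep
    M->M probabilities near one).  Residues outside the alphabet (e.g. ``X``)
    count towards column occupancy but contribute no emission counts.
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    if transition_smoothing <= 0:
        raise ValueError("transition_smoothing must be positive")
    K = len(alphabet)
    if background is None:
        background = uniform_background(alphabet)
    background = np.asarray(background, dtype=float)
    if background.shape != (K,) or np.any(background <= 0):
        raise ValueError("background must be strictly positive over the alphabet")
    background = background / background.sum()

    n, ncols = alignment.n_rows, alignment.n_cols
    if weighting == "uniform":
        weights = np.full(n, 1.0)
    elif weighting == "henikoff":
        weights = henikoff_weights(alignment)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    index = {a: i for i, a in enumerate(alphabet)}
    rows = [rec.residues for rec in alignment.members]

    occupancy = np.zeros(ncols)
    for row, w in zip(rows, weights):
        for j, ch in enumerate(row):
            if ch != GAP:
                occupancy[j] += w
    total_w = weights.sum()
    match_cols = tuple(j for j in range(ncols) if occupancy[j] > 0.5 * total_w)
    L = len(match_cols)
    if L == 0:
        raise ValueError("no match states: every column is at most 50 % occupied")

    # emissions
    counts = np.zeros((L, K))
    for row, w in zip(rows, weights):
        for m, j in enumerate(match_cols):
            ch = row[j]
            if ch in index:
                counts[m, index[ch]] += w
    totals = counts.sum(axis=1, keepdims=True)
    match_emissions = (counts + pseudocount_weight * background) / (
        totals + pseudocount_weight
    )
    insert_emissions = np.tile(background, (L, 1))

    # transitions from observed state paths, +1 smoothing
    is_match = [False] * ncols
    for j in match_cols:
        is_match[j] = True

    tcounts = np.full((L + 1, 7), transition_smoothing)  # add-constant smoothing
    for row, w in zip(rows, weights):
        prev_state, prev_node = "M", 0  # begin node behaves like a match state
        events: list[tuple[str, int]] = []
        node = 0
        for j in range(ncols):
            ch = row[j]
            if is_match[j]:
                node += 1
                events.append(("M" if ch != GAP else "D", node))
            elif ch != GAP:
                events.append(("I", node))
        events.append(("M", L + 1))  # virtual end, entered as a match
        for state, at in events:
            key = prev_state + state
            col = {
                "MM": T_MM,
                "MI": T_MI,
                "MD": T_MD,
                "IM": T_IM,
                "II": T_II,
                "DM": T_DM,
                "DD": T_DD,
            }.get(key)
            if col is not None:  # I<->D steps are not modelled (Plan7)
                tcounts[prev_node, col] += w
            prev_state, prev_node = state, at

    transitions = np.zeros_like(tcounts)
    for out in (_M_OUT, _I_OUT, _D_OUT):
        cols = list(out)
        transitions[:, cols] = tcounts[:, cols] / tcounts[:, cols].sum(
            axis=1, keepdims=True
        )

    hmm = ProfileHMM(
        name=name or alignment.members[0].id,
        alphabet=alphabet,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=background,
        n_seqs=n,
        match_columns=match_cols,
    )
    hmm.validate()
    return hmm


def shuffle_hmm(hmm: ProfileHMM, seed: int) -> ProfileHMM:
    """Return a decoy with match columns permuted uniformly at random.

    The multiset of emission columns is preserved; each position's
    transition row travels with its column.  Requires ``L >= 2``.
    """
    if hmm.L < 2:
        raise ValueError("cannot shuffle an HMM with fewer than 2 match states")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(hmm.L)
    transitions = hmm.transitions.copy()
    transitions[1:, :] = hmm.transitions[1:, :][perm, :]
    shuffled = ProfileHMM(
        name=f"{hmm.name}|shuffle",
        alphabet=hmm.alphabet,
        match_emissions=hmm.match_emissions[perm, :].copy(),
        insert_emissions=hmm.insert_emissions[perm, :].copy(),
        transitions=transitions,
        background=hmm.background,
        n_seqs=hmm.n_seqs,
        match_columns=tuple(hmm.match_columns[i] for i in perm),
    )
    shuffled.validate()
    return shuffled
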