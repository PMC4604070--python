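"""Tajima's neutrality test on a group alignment.

The statistic contrasts mean pairwise diversity with the Watterson
estimate:

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S - 1))

with a1 = sum 1/i, a2 = sum 1/i^2 (i = 1..n-1), b1 = (n+1)/(3(n-1)),
b2 = 2(n^2 + n + 3)/(9n(n-1)), c1 = b1 - 1/a1,
c2 = b2 - (n+2)/(a1*n) + a2/a1^2, e1 = c1/a1, e2 = c2/(a1^2 + a2).

Columns containing gaps or ambiguity codes are excluded listwise from both
S and pi.  The implementation is alphabet-agnostic: any discrete state set
(amino acid, nucleotide, binary) is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .formats import Alignment

__all__ = ["TajimaResult", "tajima_d", "AMBIGUOUS_STATES"]

AMBIGUOUS_STATES = frozenset("-.XNxn?*")


@dataclass(frozen=True)
class TajimaResult:
    n: int
    n_sites_used: int
    S: int
    pi: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float  # NaN when undefined (S == 0)

    @property
    def d_defined(self) -> bool:
        return not math.isnan(self.D)


def tajima_d(alignment: Alignment) -> TajimaResult:
    """Compute Tajima's D and all intermediate quantities.

    Requires at least three sequences.  When no site segregates, D is
    undefined and returned as NaN (flagged, not raised).
    """
    n = alignment.n_rows
    if n < 3:
        raise ValueError(f"group too small for the neutrality test (n={n} < 3)")

    usable = [
        j
        for j in range(alignment.n_cols)
        if not any(ch in AMBIGUOUS_STATES for ch in alignment.column(j))
    ]

    S = 0
    pair_diffs_total = 0.0
    n_pairs = n * (n - 1) / 2.0
    for j in usable:
        col = alignment.column(j)
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        if len(counts) > 1:
            S += 1
            same = sum(c * (c - 1) / 2.0 for c in counts.values())
            pair_diffs_total += n_pairs - same
    pi = pair_diffs_total / n_pairs

    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)

    variance = e1 * S + e2 * S * (S - 1.0)
    if S > 0 and variance > 0:
        D = (pi - S / a1) / math.sqrt(variance)
    else:
        # S == 0, or a degenerate variance (n = 3 with S = 1 gives c1 = 0)
        D = float("nan")

    return TajimaResult(
        n=n,
        n_sites_used=len(usable),
        S=S,
        pi=pi,
        a1=a1,
        a2=a2,
        b1=b1,
        b2=b2,
        c1=c1,
        c2=c2,
        e1=e1,
        e2=e2,
        D=D,
    )
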