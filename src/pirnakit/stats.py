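"""Shared statistical primitives: 2x2 Fisher tests and rank-sum tests.

The rank-sum test implements an exact path by full enumeration over
combinations (midrank handling of ties), because small precursor-length
comparisons are tie-heavy and the standard exact Mann-Whitney distribution
assumes continuity. Larger comparisons use the tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    corrected: bool  # Haldane correction applied to the OR (zero cell)


def fisher_2x2(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> FisherResult:
    """Fisher's exact test on the table [[a, b], [c, d]].

    The odds ratio is the sample OR (a*d)/(b*c) with the Haldane +0.5
    correction applied to every cell when any cell is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if 0 in (a + b, c + d, a + c, b + d):
        raise ValueError("empty table margin")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    corrected = 0 in (a, b, c, d)
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    return FisherResult(float(aa * dd / (bb * cc)), float(p), corrected)


def _rank_sum_stat(pooled_ranks: np.ndarray, idx_a: tuple[int, ...]) -> float:
    return float(pooled_ranks[list(idx_a)].sum())


def rank_sum_test(
    a, b, alternative: str = "two-sided", exact_limit: int = 10_000
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by full enumeration (ties via midranks) when ``len(a)*len(b) <=
    exact_limit``; otherwise the tie-corrected normal approximation with
    continuity correction. ``alternative`` 'greater' means a tends larger
    than b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    n, m = len(a), len(b)
    if n * m <= exact_limit and comb(n + m, n) <= 2_000_000:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        w_obs = ranks[:n].sum()
        total = 0
        n_ge = 0
        n_le = 0
        n_eq = 0
        for idx in combinations(range(n + m), n):
            w = ranks[list(idx)].sum()
            total += 1
            if w >= w_obs - 1e-9:
                n_ge += 1
            if w <= w_obs + 1e-9:
                n_le += 1
        p_greater = n_ge / total
        p_less = n_le / total
        if alternative == "greater":
            return p_greater
        if alternative == "less":
            return p_less
        return min(1.0, 2 * min(p_greater, p_less))
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.pvalue)
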