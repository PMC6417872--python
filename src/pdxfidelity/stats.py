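"""Shared statistical helpers.

The one-sided rank-sum (Wilcoxon/Mann-Whitney) test used to compare
matched-pair correlations against unmatched-pair correlations. Small group
configurations are evaluated by exact enumeration over all rank
assignments (mid-ranks for ties); larger ones fall back to the normal
approximation with tie correction.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

# enumeration cost cap: C(n1+n2, n1) assignments
_EXACT_LIMIT = 200_000


def rank_sum_test(greater: np.ndarray, lesser: np.ndarray, exact_limit: int = _EXACT_LIMIT) -> float:
    """One-sided rank-sum p-value for H1: `greater` stochastically > `lesser`.

    Pools both samples, assigns mid-ranks, and computes
    P(rank sum of group 1 >= observed) exactly when the number of rank
    assignments is tractable, otherwise via the tie-corrected normal
    approximation (``scipy.stats.mannwhitneyu``).
    """
    x = np.asarray(greater, dtype=float)
    y = np.asarray(lesser, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    if comb(n1 + n2, n1) <= exact_limit:
        return _exact_rank_sum(x, y)
    res = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def _exact_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    n1 = x.size
    n = pooled.size
    observed = ranks[:n1].sum()
    total = 0
    at_least = 0
    for idx in combinations(range(n), n1):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            at_least += 1
    return at_least / total


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to `decimals` places (2160/2414 -> 89.5)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    q = Decimal(str(100.0 * numerator / denominator))
    exp = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def percent_truncated(numerator: float, denominator: float) -> int:
    """Percentage truncated to an integer (90/104 -> 86)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return int(100.0 * numerator / denominator)
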