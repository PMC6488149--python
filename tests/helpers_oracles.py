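"""Independent brute-force oracles used to check the statistical core.

Each oracle recomputes a p-value or interval by direct enumeration/summation,
deliberately avoiding the code paths (tail functions, binary searches, DP
tables) used by the implementation under test.
"""

from __future__ import annotations

import math
from itertools import combinations
from math import comb

import numpy as np
from scipy.special import gammaln
from scipy.stats import rankdata

REL = 10**7  # integer encoding of the 1 + 1e-7 probability-tie tolerance


def poisson_two_sided_oracle(x: int, mu: float) -> float:
    """Sum Poisson pmf terms over all outcomes no more probable than x."""
    if mu == 0:
        return 1.0 if x == 0 else 0.0
    kmax = int(mu + 20.0 * math.sqrt(mu) + 200.0) + x
    k = np.arange(kmax + 1)
    pmf = np.exp(k * np.log(mu) - mu - gammaln(k + 1))
    d = pmf[x] * (1.0 + 1e-7)
    return min(1.0, float(pmf[pmf <= d].sum()))


def poisson_interval_oracle(mu: float, level: float = 0.95) -> tuple[int, int]:
    """Scan the CDF for the central interval boundaries."""
    if mu == 0:
        return (0, 0)
    alpha = (1.0 - level) / 2.0
    kmax = int(mu + 20.0 * math.sqrt(mu) + 200.0)
    k = np.arange(kmax + 1)
    pmf = np.exp(k * np.log(mu) - mu - gammaln(k + 1))
    cdf = np.cumsum(pmf)
    lo = 0
    while lo + 1 <= kmax and cdf[lo + 1 - 1] <= alpha:  # cdf(lo-1) <= alpha
        lo += 1
    hi = 0
    while cdf[hi] < 1.0 - alpha:
        hi += 1
    return (lo, hi)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Full hypergeometric enumeration in exact integer arithmetic."""
    row1, row2, col1 = a + b, c + d, a + c
    lo, hi = max(0, col1 - row2), min(row1, col1)
    weights = {k: comb(row1, k) * comb(row2, col1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w * REL <= w_obs * (REL + 1))
    return num / sum(weights.values())


def mannwhitney_permutation_oracle(a, b) -> float:
    """Enumerate every group assignment; double the smaller rank-sum tail."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n = len(a)
    ranks = rankdata(pooled)
    w_obs = ranks[: n].sum()
    sums = np.array(
        [ranks[list(ix)].sum() for ix in combinations(range(len(pooled)), n)]
    )
    p_le = float((sums <= w_obs + 1e-9).mean())
    p_ge = float((sums >= w_obs - 1e-9).mean())
    return min(1.0, 2.0 * min(p_le, p_ge))
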