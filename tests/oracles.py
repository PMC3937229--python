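"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — exact rational/enumeration
arithmetic and O(n^2) scans — and shares no code path with the package.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p for [[a, b], [c, d]] by exact tail sum.

    Hypergeometric: fix margins, sum P(table) over tables with top-left
    cell >= a.  Exact integer arithmetic until the final division.
    """
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    num = 0
    for k in range(a, min(row1, col1) + 1):
        if row1 - k > n - col1:
            continue
        num += comb(col1, k) * comb(n - col1, row1 - k)
    return num / comb(n, row1)


def fisher_twosided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of all table probabilities <= P(observed).

    Uses the same relative tolerance (1 + 1e-7) as the conventional
    implementation when comparing probabilities.
    """
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    denom = comb(n, row1)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    probs = {k: comb(col1, k) * comb(n - col1, row1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def hypergeom_sf_oracle(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n), exact tail sum."""
    total = 0
    for j in range(k, min(K, n) + 1):
        if n - j > M - K:
            continue
        total += comb(K, j) * comb(M - K, n - j)
    return total / comb(M, n)


def mwu_twosided_oracle(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Valid for tie-free data.  p = min(1, 2 * min(P(U <= u), P(U >= u)))
    where U is group a's statistic.
    """
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(a)
    u_obs = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n_a):
        r = sum(i + 1 for i in idx)
        us.append(r - n_a * (n_a + 1) / 2)
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


def bh_oracle(pvals):
    """BH step-up via statsmodels (reference implementation)."""
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        return np.empty(0)
    return multipletests(pvals, method="fdr_bh")[1]


def window_cluster_oracle(positions, window: int, min_sites: int):
    """Greedy fixed-window clustering, naive list-based rewrite.

    Returns (start, end, n) tuples over one chromosome's sorted positions;
    a cluster's spanned width (max - min + 1) must stay <= window.
    """
    pos = sorted(positions)
    clusters = []
    i = 0
    while i < len(pos):
        j = i
        while j + 1 < len(pos) and pos[j + 1] - pos[i] + 1 <= window:
            j += 1
        if j - i + 1 >= min_sites:
            clusters.append((pos[i], pos[j], j - i + 1))
            i = j + 1
        else:
            i += 1
    return clusters


def overlap_pairs_oracle(extents_a, extents_b):
    """All-pairs >= 1 nt overlap between 1-based inclusive extents."""
    pairs = []
    for i, (ca, sa, ea) in enumerate(extents_a):
        for j, (cb, sb, eb) in enumerate(extents_b):
            if ca == cb and sa <= eb and sb <= ea:
                pairs.append((i, j))
    return pairs


def gaussian_sum_oracle(sites, xs, sigma):
    """Direct full summation of the Gaussian kernel density."""
    sites = np.asarray(sites, float)
    return np.array([np.exp(-0.5 * ((x - sites) / sigma) ** 2).sum() for x in np.asarray(xs, float)])
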