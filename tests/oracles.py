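"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by the most literal method
available (per-base boolean arrays, direct tail summation, exhaustive
enumeration) and never shares code with the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def per_base_coverage(intervals, length: int) -> np.ndarray:
    """Boolean per-base coverage of [0, length) for single-chromosome input."""
    cov = np.zeros(length, dtype=bool)
    for iv in intervals:
        cov[iv.start : iv.end] = True
    return cov


def poisson_tail(k: int, lam: float, terms: int = 4000) -> float:
    """P(X >= k) for X ~ Poisson(lam) by direct summation of the pmf."""
    if k <= 0:
        return 1.0
    # sum the lower tail and subtract for stability at small k
    log_pmf = -lam
    lower = 0.0
    for i in range(k):
        if i > 0:
            log_pmf += math.log(lam) - math.log(i)
        lower += math.exp(log_pmf)
    return max(0.0, 1.0 - lower)


def poisson_upper_tail_direct(k: int, lam: float, cutoff: float = 1e-18) -> float:
    """P(X >= k) summed upward from k (accurate for tiny tails)."""
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    total = 0.0
    i = k
    while True:
        term = math.exp(log_term)
        total += term
        if term < cutoff * max(total, 1e-300) and i > lam + k:
            break
        i += 1
        log_term += math.log(lam) - math.log(i)
        if i > k + 10000:
            break
    return total


def hypergeom_tail(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M population, n successes, N draws),
    by direct summation of binomial-coefficient ratios."""
    total = 0.0
    for i in range(k, min(n, N) + 1):
        total += (
            math.comb(n, i) * math.comb(M - n, N - i) / math.comb(M, N)
        )
    return total


def ranksum_exact_p(x, y) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of all assignments."""
    pooled = np.concatenate([x, y])
    n = len(pooled)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    obs = ranks[: len(x)].sum()
    mean = len(x) * (n + 1) / 2.0
    count = 0
    total = 0
    for combo in combinations(range(n), len(x)):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def gsea_es_enumeration(stats_desc, in_set, weight: float):
    """Running-sum extremes by a literal step-by-step enumeration.

    Returns (best_pos, best_neg): the maximal and minimal deviation of
    the running sum. The enrichment score is whichever has the larger
    magnitude (a mathematically exact tie is sign-ambiguous).
    """
    n = len(stats_desc)
    n_hit = int(np.sum(in_set))
    weights = [abs(s) ** weight if h else 0.0 for s, h in zip(stats_desc, in_set)]
    wsum = sum(weights)
    running = 0.0
    best_pos = 0.0
    best_neg = 0.0
    for i in range(n):
        if in_set[i]:
            running += weights[i] / wsum if wsum > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    return best_pos, best_neg
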