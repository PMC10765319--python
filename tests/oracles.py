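"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive: explicit loops, itertools enumeration, and
hand-rolled rank computation, sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def average_ranks(values) -> list[float]:
    """1-based ranks with ties sharing the average rank (hand-rolled)."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_factor_bruteforce(y_j, y_r, trim_m=0.30, trim_a=0.05) -> float:
    """Trimmed weighted-mean-of-M TMM factor of sample j against reference r.

    Direct evaluation: per-gene M, A and asymptotic-variance weights over
    genes positive in both samples, rank-based double trimming, then the
    precision-weighted mean of the surviving M values.
    """
    N_j = float(sum(y_j))
    N_r = float(sum(y_r))
    rows = [
        (yj, yr) for yj, yr in zip(y_j, y_r) if yj > 0 and yr > 0
    ]
    M, A, W = [], [], []
    for yj, yr in rows:
        pj, pr = yj / N_j, yr / N_r
        M.append(math.log2(pj / pr))
        A.append(0.5 * math.log2(pj * pr))
        W.append(1.0 / ((N_j - yj) / (N_j * yj) + (N_r - yr) / (N_r * yr)))
    n = len(M)
    rM = average_ranks(M)
    rA = average_ranks(A)
    loM, hiM = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    loA, hiA = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    num = den = 0.0
    for g in range(n):
        if loM <= rM[g] <= hiM and loA <= rA[g] <= hiA:
            num += W[g] * M[g]
            den += W[g]
    if den == 0:
        return 1.0
    return 2.0 ** (num / den)


def ranksum_exact_p(x, y) -> float:
    """Exact two-sided rank-sum p-value by full enumeration (no ties).

    Enumerates every split of the pooled sample into groups of the observed
    sizes and counts splits whose rank sum is at least as extreme (two-sided
    via min(1, 2·min tail))."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = average_ranks(pooled)
    obs = sum(ranks[:n1])
    stats = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), n1)
    ]
    total = len(stats)
    p_ge = sum(1 for s in stats if s >= obs) / total
    p_le = sum(1 for s in stats if s <= obs) / total
    return min(1.0, 2.0 * min(p_ge, p_le))


def bh_stepup(pvals) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def nb_moment_dispersion(counts: np.ndarray, mean: np.ndarray) -> float:
    """Method-of-moments NB dispersion: Var = μ + φ·μ²."""
    resid_var = np.mean((counts - mean) ** 2 - mean)
    return float(resid_var / np.mean(mean**2))
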