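"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the Fisher oracle
enumerates the hypergeometric distribution directly with binomial
coefficients, and the enrichment oracle walks the running sum explicitly.
"""

from __future__ import annotations

from math import comb

import numpy as np


def fisher_exact_enumeration(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums the probability of every table with the same margins whose
    probability does not exceed that of the observed table
    (minimum-likelihood convention).
    """
    r1 = n11 + n10
    c1 = n11 + n01
    n = n11 + n10 + n01 + n00
    denom = comb(n, c1)

    def pmf(k: int) -> float:
        return comb(r1, k) * comb(n - r1, c1 - k) / denom

    p_obs = pmf(n11)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def running_sum_score(expr: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Explicit single-sample weighted running-sum enrichment statistic."""
    n = len(expr)
    n_in = int(in_set.sum())
    if n_in == n:
        return 0.0
    ranks = np.empty(n)
    order_vals = np.argsort(expr)
    # average ranks, ascending (1 = lowest)
    sorted_vals = expr[order_vals]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order_vals[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    walk = sorted(range(n), key=lambda g: (-expr[g], str(g)))
    total_w = sum(ranks[g] ** tau for g in walk if in_set[g])
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in walk:
        if in_set[g]:
            cum_in += ranks[g] ** tau / total_w
        else:
            cum_out += 1
        score += cum_in - cum_out / (n - n_in)
    return score


def mean_abs_pairwise_r(m: np.ndarray) -> float:
    """Mean |Pearson r| over distinct row pairs, zero-variance rows -> r=0."""
    k = m.shape[0]
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            si, sj = m[i].std(), m[j].std()
            if si == 0 or sj == 0:
                vals.append(0.0)
            else:
                vals.append(abs(float(np.corrcoef(m[i], m[j])[0, 1])))
    return float(np.mean(vals))
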