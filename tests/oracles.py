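"""Independent brute-force oracles used to verify the implementations.

Everything here is written as a plain, slow, transparent computation
(pure-Python walks and exhaustive enumeration) and never calls into the
package's own numerics.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def es_bruteforce(genes, scores, members, weight_exponent):
    """Walk the full ranking and take the signed maximal deviation."""
    n = len(genes)
    hits = [g in members for g in genes]
    k = sum(hits)
    assert 0 < k < n
    total = sum(abs(s) ** weight_exponent for s, h in zip(scores, hits) if h)
    run = 0.0
    values = []
    for i in range(n):
        if hits[i]:
            if total == 0:
                run += 1.0 / k
            else:
                run += abs(scores[i]) ** weight_exponent / total
        else:
            run -= 1.0 / (n - k)
        values.append(run)
    hi = max(values)
    lo = min(min(values), 0.0)
    # magnitude ties go to the positive deviation (tolerance guards float noise)
    return hi if abs(hi) >= abs(lo) - 1e-9 else lo


def bh_bruteforce(pvalues):
    """Step-up Benjamini-Hochberg from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(pvalues[i] * m / rank, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def hypergeom_enum(universe, annotation, query):
    """P(overlap >= observed) by enumerating all draws of |query| genes."""
    universe = sorted(universe)
    annotation = set(annotation) & set(universe)
    observed = len(set(query) & annotation)
    n_draw = len(query)
    hits = 0
    total = 0
    for draw in combinations(universe, n_draw):
        total += 1
        if len(set(draw) & annotation) >= observed:
            hits += 1
    return len(set(query) & annotation), hits / total


def mannwhitney_enum(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    U counts pairs (x_i, y_j) with x_i > y_j plus half the ties; the
    two-sided p-value is the probability of a U at least as far from
    n1*n2/2 as observed.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_stat(a_idx):
        a = [pooled[i] for i in a_idx]
        b = [pooled[i] for i in range(n1 + n2) if i not in set(a_idx)]
        u = 0.0
        for xi in a:
            for yj in b:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    center = n1 * n2 / 2
    u_obs = u_stat(tuple(range(n1)))
    dev = abs(u_obs - center)
    hits = sum(
        1 for idx in combinations(range(n1 + n2), n1) if abs(u_stat(idx) - center) >= dev - 1e-12
    )
    return u_obs, hits / comb(n1 + n2, n1)


def ks_statistic(hit_ranks, miss_ranks):
    """Two-sample KS statistic between hit and miss rank distributions."""
    all_points = sorted(set(hit_ranks) | set(miss_ranks))
    n_h, n_m = len(hit_ranks), len(miss_ranks)
    best = 0.0
    for t in all_points:
        f_h = sum(1 for r in hit_ranks if r <= t) / n_h
        f_m = sum(1 for r in miss_ranks if r <= t) / n_m
        best = max(best, abs(f_h - f_m))
    return best
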