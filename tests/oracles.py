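"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — enumeration and nested loops — and
shares no code with the package under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def hypergeom_prob(a: int, row1: int, col1: int, n: int) -> float:
    """P(top-left cell = a) for fixed margins row1, col1, total n."""
    return comb(row1, a) * comb(n - row1, col1 - a) / comb(n, col1)


def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher p by full enumeration over the support."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom_prob(a, row1, col1, n)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = hypergeom_prob(x, row1, col1, n)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def mann_whitney_exact_enum(x, y) -> float:
    """Two-sided exact Mann–Whitney p by enumerating all rank splits.

    Assumes no ties across the pooled sample.
    """
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    rx = sum(ranks[v] for v in x)
    u_obs = rx - nx * (nx + 1) / 2
    mean_u = nx * ny / 2
    dev_obs = abs(u_obs - mean_u)
    total = comb(nx + ny, nx)
    count = 0
    all_ranks = list(range(1, nx + ny + 1))
    for subset in combinations(all_ranks, nx):
        u = sum(subset) - nx * (nx + 1) / 2
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


def comutation_counts_naive(profiles: list[set[str]]):
    """Pairwise shared-gene counts by explicit nested loops."""
    n = len(profiles)
    out = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i][j] = len(profiles[i])
            else:
                out[i][j] = sum(1 for g in profiles[i] if g in profiles[j])
    return out
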