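"""Independent brute-force oracles used to verify the statistical kernels.

These deliberately share no code with the package: exact rational
arithmetic (fractions + math.comb) for Fisher tests, a literal step-up
scan for the FDR adjustment, and scipy's Pearson on explicitly permuted
rank vectors for the Spearman permutation p-value.
"""

from fractions import Fraction
from itertools import permutations
from math import comb, factorial

import numpy as np
from scipy import stats

#: relative tie tolerance of the point-probability rule under test
TIE_TOL = Fraction(1, 10**7)


def fisher_2x2_oracle(table) -> float:
    """Two-sided Fisher p on a 2x2 table via exact rational enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    if n == 0:
        return 1.0
    denom = comb(n, r1)
    p_obs = Fraction(comb(c1, a) * comb(n - c1, b), denom)
    cutoff = p_obs * (1 + TIE_TOL)
    total = Fraction(0)
    for a2 in range(max(0, c1 - r2), min(c1, r1) + 1):
        p = Fraction(comb(c1, a2) * comb(n - c1, r1 - a2), denom)
        if p <= cutoff:
            total += p
    return float(min(total, Fraction(1)))


def fisher_2x3_oracle(table) -> float:
    """Two-sided Fisher p on a 2x3 table via exact rational enumeration."""
    top, bottom = table
    cols = [t + b for t, b in zip(top, bottom)]
    r1 = sum(top)
    n = sum(cols)
    if n == 0:
        return 1.0
    denom = comb(n, r1)
    p_obs = Fraction(
        comb(cols[0], top[0]) * comb(cols[1], top[1]) * comb(cols[2], top[2]), denom
    )
    cutoff = p_obs * (1 + TIE_TOL)
    total = Fraction(0)
    for a in range(0, min(cols[0], r1) + 1):
        for b in range(0, min(cols[1], r1 - a) + 1):
            c = r1 - a - b
            if 0 <= c <= cols[2]:
                p = Fraction(comb(cols[0], a) * comb(cols[1], b) * comb(cols[2], c), denom)
                if p <= cutoff:
                    total += p
    return float(min(total, Fraction(1)))


def bh_oracle(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted values by the literal min-over-suffix rule."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_i, m)]
        q[idx] = min(1.0, min(candidates))
    return q


def spearman_exact_oracle(x, y) -> tuple[float, float]:
    """(rho, two-sided exact permutation p) via scipy Pearson on mid-ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = stats.pearsonr(rx, ry).statistic
    n = len(rx)
    hits = sum(
        1
        for perm in permutations(ry)
        if abs(stats.pearsonr(rx, np.array(perm)).statistic) >= abs(rho) - 1e-12
    )
    return float(rho), hits / factorial(n)
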