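"""Independent brute-force oracles used by the test suite.

These stay deliberately naive (exact rational arithmetic, full
enumeration) and never share code with the implementation they check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the exact (Fraction) probabilities of every table with the
    observed margins whose probability does not exceed the observed
    table's.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


def mannwhitney_two_sided_oracle(x, y) -> float:
    """Exact two-sided Mann-Whitney p by full label-assignment enumeration.

    Assumes tie-free data.  Enumerates every way of assigning the pooled
    values to the first group, computes the U statistic for each, and sums
    the probabilities of both tails at least as extreme as observed.
    """
    x, y = list(map(float, x)), list(map(float, y))
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    m = n1 * len(y)

    def u_stat(group1, rest):
        return sum(1 for xi in group1 for yj in rest if xi > yj)

    u_obs = u_stat(x, y)
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    pooled_set = set(pooled)
    count = 0
    total = 0
    for group1 in combinations(pooled, n1):
        rest = list(pooled_set - set(group1))
        u = u_stat(group1, rest)
        if u <= lo or u >= hi:
            count += 1
        total += 1
    return min(1.0, count / total)


def auc_pair_ordering_oracle(case_scores, control_scores) -> float:
    """AUC as the probability a random case outranks a random control,
    with half credit for ties (the Mann-Whitney U formulation)."""
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    wins = 0.0
    for cs in case_scores:
        wins += (cs > control_scores).sum() + 0.5 * (cs == control_scores).sum()
    return wins / (len(case_scores) * len(control_scores))
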