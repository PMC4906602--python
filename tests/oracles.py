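"""Independent brute-force oracles shared by the test suite.

Each function re-derives a statistic by enumeration or base-by-base
bookkeeping, with no code shared with the implementation it checks.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy import stats


def brute_force_tau(values):
    """Tissue-specificity index by direct summation."""
    m = max(values)
    return sum(1 - v / m for v in values) / (len(values) - 1)


def fisher_oracle(table):
    """Exact-rational enumeration of all 2x2 tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(x) <= p_obs:
            total += pmf(x)
    return float(total)


def kendall_oracle(x, y):
    """O(n^2) enumeration of concordant/discordant/tied pairs (tau-b)."""
    n = len(x)
    C = D = n1 = n2 = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            n1 += 1
            n2 += 1
        elif dx == 0:
            n1 += 1
        elif dy == 0:
            n2 += 1
        elif dx * dy > 0:
            C += 1
        else:
            D += 1
    n0 = n * (n - 1) // 2
    return (C - D) / np.sqrt((n0 - n1) * (n0 - n2))


def containment_oracle(cns_list, regions):
    """Base-by-base strict-containment counting for one gene's regions."""
    counts = {k: 0 for k in regions.intervals}
    sums = {k: 0 for k in regions.intervals}
    for rec in cns_list:
        if rec.chrom != regions.chrom:
            continue
        bases = set(range(rec.start, rec.end))
        for region_class, intervals in regions.intervals.items():
            for s, e in intervals:
                if bases <= set(range(s, e)):
                    counts[region_class] += 1
                    sums[region_class] += len(bases)
                    break
    return counts, sums


def signed_rank_oracle(diffs):
    """Full 2^n sign-assignment enumeration of the Wilcoxon statistic."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_le = (ws <= w_obs + 1e-9).mean()
    p_ge = (ws >= w_obs - 1e-9).mean()
    return w_obs, min(1.0, 2 * min(p_le, p_ge))
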