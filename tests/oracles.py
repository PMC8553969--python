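"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's implementations (and scipy's
rankdata/kruskal): ranks are computed by explicit position averaging and
the statistic by direct summation, so they are an independent check.
"""

import itertools
import math


def average_ranks(values):
    """Ranks 1..N with average ranks for ties, by explicit enumeration."""
    n = len(values)
    ranks = [0.0] * n
    order = sorted(range(n), key=lambda i: values[i])
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1      # positions i..j (0-based) -> mean rank
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kw_statistic_oracle(values, groups):
    """Tie-corrected Kruskal-Wallis H by direct summation."""
    n = len(values)
    ranks = average_ranks(values)
    by_group = {}
    for r, g in zip(ranks, groups):
        by_group.setdefault(g, []).append(r)
    mean_rank = (n + 1) / 2
    num = 0.0
    for rs in by_group.values():
        gbar = sum(rs) / len(rs)
        num += len(rs) * (gbar - mean_rank) ** 2
    h = 12.0 / (n * (n + 1)) * num
    tie = 0.0
    for v in set(values):
        t = values.count(v) if isinstance(values, list) else list(values).count(v)
        tie += t**3 - t
    denom = 1.0 - tie / (n**3 - n)
    if denom <= 0:
        return 0.0
    return h / denom


def kw_permutation_p(values, groups):
    """Exact permutation p-value of H (all distinct label assignments)."""
    observed = kw_statistic_oracle(values, groups)
    count = total = 0
    for perm in set(itertools.permutations(groups)):
        h = kw_statistic_oracle(values, list(perm))
        total += 1
        if h >= observed - 1e-12:
            count += 1
    return count / total


def selection_probability_closed_form(p_cut=1e-2, product_cut=1e-5):
    """P(p1<c, p2<c, p1*p2<q) for iid uniform p-values, q < c^2."""
    c, q = p_cut, product_cut
    return q * (1 + math.log(c * c / q))
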