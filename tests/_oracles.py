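"""Independent brute-force oracles used to cross-check the statistics.

Everything here is written from the definitions (midranks by hand,
enumeration of labelings/permutations, direct PMF summation, the
sorted-minimum form of Benjamini-Hochberg) and deliberately shares no
code with the package.
"""

from __future__ import annotations

import itertools
import math


def midranks(values):
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return float("nan") if den == 0 else num / den


def spearman_rho(x, y):
    return pearson(midranks(list(x)), midranks(list(y)))


def spearman_perm_p(x, y):
    """Two-sided permutation p-value by enumerating all orderings of y."""
    rho = spearman_rho(x, y)
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_rho(x, perm)) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total


def mannwhitney_u(case, control):
    n1 = len(case)
    ranks = midranks(list(case) + list(control))
    return sum(ranks[:n1]) - n1 * (n1 + 1) / 2


def mannwhitney_enum_p(case, control):
    """Two-sided p by enumerating every assignment of group labels."""
    n1, n2 = len(case), len(control)
    pooled = list(case) + list(control)
    ranks = midranks(pooled)
    mu = n1 * n2 / 2
    u_obs = mannwhitney_u(case, control)
    hits = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total


def binomial_tail_sum(k, n, p):
    """P(X >= k) by direct log-space summation of the PMF."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    total = 0.0
    lp, lq = math.log(p), math.log1p(-p)
    for i in range(k, n + 1):
        logterm = (
            math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1)
            + i * lp + (n - i) * lq
        )
        total += math.exp(logterm)
    return min(total, 1.0)


def bh_sorted_min(p_values):
    """q_i = min over j with p_(j) >= p_(i) of p_(j) * m / j, capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p_values[idx] * m / rank)
        q[idx] = running
    return q
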