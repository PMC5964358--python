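"""Independent brute-force oracles used by the test suite.

These stay deliberately naive: full enumeration or direct formula
evaluation, never sharing code with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign patterns.

    Assumes no zero differences and no ties among |diffs|.
    """
    d = np.asarray(diffs, dtype=float)
    absd = np.abs(d)
    ranks = np.argsort(np.argsort(absd)) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [np.sum(ranks[np.array(signs, dtype=bool)]) for signs in product([0, 1], repeat=n)]
    )
    cdf = np.mean(ws <= w_obs)
    sf = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(cdf, sf))


def mannwhitney_exact_p(x, y) -> float:
    """Two-sided Mann-Whitney p by enumerating all rank splits (no ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n, m = len(x), len(y)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    us = []
    for idx in combinations(range(n + m), n):
        r = ranks[list(idx)].sum() - n * (n + 1) / 2.0
        us.append(r)
    us = np.array(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(cdf, sf))


def anova_f(values, labels) -> float:
    """Classic one-way ANOVA F from group means."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = values.mean()
    groups = [values[labels == g] for g in np.unique(labels)]
    a = len(groups)
    n = len(values)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def pairwise_identity(a: str, b: str) -> float:
    """Needleman-Wunsch identity (matches / alignment columns) by dynamic
    programming with unit costs — the oracle for the edlib-backed path."""
    n, m = len(a), len(b)
    # dp over (cost); traceback to count columns and matches
    cost = np.zeros((n + 1, m + 1), dtype=int)
    cost[:, 0] = np.arange(n + 1)
    cost[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = cost[i - 1, j - 1] + (a[i - 1] != b[j - 1])
            cost[i, j] = min(sub, cost[i - 1, j] + 1, cost[i, j - 1] + 1)
    i, j, cols, matches = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and cost[i, j] == cost[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and cost[i, j] == cost[i - 1, j] + 1:
            i -= 1
        else:
            j -= 1
        cols += 1
    return matches / cols
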