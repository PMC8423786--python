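"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity from first principles (explicit
loops, enumeration, closed forms), deliberately avoiding the code paths
under test.
"""
from __future__ import annotations

import math

import numpy as np
import scipy.stats


def welch_formula(x, y):
    """Direct evaluation of Welch's statistic and the Student-t tail."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1 = sum((xi - x.mean()) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - y.mean()) ** 2 for yi in y) / (n2 - 1)
    t = (x.mean() - y.mean()) / math.sqrt(v1 / n1 + v2 / n2)
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    p = 2 * scipy.stats.t.sf(abs(t), df)
    return t, p


def bh_step_up(p):
    """q(i) = min_{j >= i} p(j) * m / j over the sorted p-values."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def hypergeom_tail(a, b, c, d):
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+b, n=a+c), by
    enumeration of every achievable overlap."""
    N, K, n = a + b + c + d, a + b, a + c
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(a, min(K, n) + 1)
        if n - x <= N - K
    ) / total


def yates_statistic(a, b, c, d):
    n = a + b + c + d
    corrected = max(abs(a * d - b * c) - n / 2, 0)
    return n * corrected**2 / ((a + b) * (c + d) * (a + c) * (b + d))


def logrank_walk(times1, events1, times2, events2):
    """Explicit risk-table walk: sum of (O - E) and hypergeometric
    variance terms at each distinct event time."""
    records = [(t, e, 1) for t, e in zip(times1, events1)] + [
        (t, e, 2) for t, e in zip(times2, events2)
    ]
    event_times = sorted({t for t, e, _ in records if e})
    o_minus_e, var = 0.0, 0.0
    for tau in event_times:
        at_risk = [(t, e, g) for t, e, g in records if t >= tau]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 1)
        d = sum(1 for t, e, _ in at_risk if t == tau and e)
        d1 = sum(1 for t, e, g in at_risk if t == tau and e and g == 1)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return stat, float(scipy.stats.chi2.sf(stat, 1))


def naive_signatures(values, gene_ids, labels, cluster, fdr=0.01):
    """Per-gene loop re-deriving both marker definitions, independent of
    the vectorized path: returns (set_A, set_B)."""
    from sigshare.stats import bh_adjust, welch_t_test

    labels = np.asarray(labels)
    in_cl = labels == cluster
    others = sorted(set(labels) - {cluster})
    p_pooled, higher_pooled = [], []
    for row in values:
        x, y = row[in_cl], row[~in_cl]
        p_pooled.append(welch_t_test(x, y).p_value)
        higher_pooled.append(x.mean() > y.mean())
    q_pooled = bh_adjust(p_pooled)
    set_a = {
        g
        for g, q, h in zip(gene_ids, q_pooled, higher_pooled)
        if h and q < fdr
    }
    passes = {g: True for g in gene_ids}
    for other in others:
        in_other = labels == other
        ps, highs = [], []
        for row in values:
            x, y = row[in_cl], row[in_other]
            ps.append(welch_t_test(x, y).p_value)
            highs.append(x.mean() > y.mean())
        qs = bh_adjust(ps)
        for g, q, h in zip(gene_ids, qs, highs):
            if not (h and q < fdr):
                passes[g] = False
    set_b = {g for g, ok in passes.items() if ok}
    return set_a, set_b


def ward2_brute_force(dist):
    """Agglomeration recomputing the Ward-2 objective at every step from
    the Lance-Williams recurrence, with exhaustive pair evaluation.
    Returns the merge sequence [(members_i, members_j, height), ...]."""
    d2 = {
        (i, j): dist[i][j] ** 2
        for i in range(len(dist))
        for j in range(i + 1, len(dist))
    }
    clusters = {i: frozenset([i]) for i in range(len(dist))}
    merges = []
    next_id = len(dist)
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for a_pos, a in enumerate(ids):
            for b in ids[a_pos + 1 :]:
                val = d2[(a, b)]
                if best is None or val < best[0]:
                    best = (val, a, b)
        val, a, b = best
        na, nb = len(clusters[a]), len(clusters[b])
        merges.append((clusters[a], clusters[b], math.sqrt(val)))
        for k in ids:
            if k in (a, b):
                continue
            nk = len(clusters[k])
            dak = d2[(min(a, k), max(a, k))]
            dbk = d2[(min(b, k), max(b, k))]
            d2[(k, next_id)] = (
                (na + nk) * dak + (nb + nk) * dbk - nk * val
            ) / (na + nb + nk)
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


def quantile_normalize_by_hand(columns):
    """Row means of the sorted columns assigned back by rank; a tie group
    receives the mean of the target values at its tied positions."""
    cols = [sorted(c) for c in columns]
    target = [sum(vals) / len(vals) for vals in zip(*cols)]
    out = []
    for col in columns:
        result = []
        for v in col:
            positions = [i for i, s in enumerate(sorted(col)) if s == v]
            result.append(sum(target[i] for i in positions) / len(positions))
        out.append(result)
    return out
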