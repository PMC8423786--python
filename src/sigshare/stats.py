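"""Scalar hypothesis tests shared across the pipeline stages.

These are the workhorse tests of the analysis: Welch's t (marker
detection), Benjamini-Hochberg step-up adjustment, the one-sided Fisher
exact test (set enrichment), the Yates-corrected 2x2 chi-square
(composition tests) and the two-group log-rank test (survival).

Degenerate inputs follow explicit conventions rather than propagating
NaN: two zero-variance groups with equal means give (statistic 0, p 1);
with different means, p 0.  A log-rank comparison with no events at all,
or with zero hypergeometric variance, gives (statistic 0, p 1).
"""
from __future__ import annotations

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import TestResult, ValidationError

__all__ = [
    "welch_t_test",
    "welch_t_from_moments",
    "bh_adjust",
    "bonferroni_adjust",
    "fisher_one_sided",
    "chi_square_yates_2x2",
    "logrank_test",
]


def welch_t_from_moments(
    mean1: np.ndarray,
    var1: np.ndarray,
    n1: int,
    mean2: np.ndarray,
    var2: np.ndarray,
    n2: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch statistic and two-sided p from group moments.

    Variances are the unbiased (ddof=1) sample variances.  Zero-variance
    pairs follow the degenerate convention described in the module
    docstring.
    """
    mean1 = np.asarray(mean1, dtype=float)
    mean2 = np.asarray(mean2, dtype=float)
    var1 = np.asarray(var1, dtype=float)
    var2 = np.asarray(var2, dtype=float)
    se2 = var1 / n1 + var2 / n2
    diff = mean1 - mean2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df_num = se2**2
        df_den = (var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1)
        df = df_num / df_den
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0.0
    equal_means = degenerate & (diff == 0.0)
    unequal_means = degenerate & (diff != 0.0)
    with np.errstate(invalid="ignore"):
        t = np.where(equal_means, 0.0, t)
        p = np.where(equal_means, 1.0, p)
        t = np.where(unequal_means, np.sign(diff) * np.inf, t)
        p = np.where(unequal_means, 0.0, p)
    return t, p


def welch_t_test(x, y) -> TestResult:
    """Two-sided Welch's t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("Welch's t-test requires at least 2 values per group")
    t, p = welch_t_from_moments(
        x.mean(), x.var(ddof=1), x.size, y.mean(), y.var(ddof=1), y.size
    )
    return TestResult(unit_id="welch", statistic=float(t), p_value=float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValidationError("2x2 table cells must be non-negative integers")
    return np.round(t).astype(np.int64)


def fisher_one_sided(table) -> TestResult:
    """One-sided (enrichment direction) Fisher exact test on a 2x2 table.

    With table [[a, b], [c, d]] the p-value is P(X >= a) for
    X ~ Hypergeometric(N = a+b+c+d, K = a+b, n = a+c): the chance of an
    overlap at least as large as observed.
    """
    t = _check_2x2(table)
    _, p = scipy.stats.fisher_exact(t, alternative="greater")
    return TestResult(unit_id="fisher", statistic=float(t[0, 0]), p_value=float(p))


def chi_square_yates_2x2(table) -> TestResult:
    """Two-sided chi-square with Yates continuity correction, df = 1.

    statistic = N * (max(|ad - bc| - N/2, 0))^2 / (m1 * m2 * n1 * n2)
    where m, n are the row and column margins.  Both margins must be
    positive on both levels.
    """
    t = _check_2x2(table).astype(float)
    a, b = t[0]
    c, d = t[1]
    n_total = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValidationError("chi-square undefined: zero row or column margin")
    corrected = max(abs(a * d - b * c) - n_total / 2.0, 0.0)
    stat = n_total * corrected**2 / (row[0] * row[1] * col[0] * col[1])
    p = float(scipy.stats.chi2.sf(stat, df=1))
    return TestResult(unit_id="chi2_yates", statistic=float(stat), p_value=p)


def logrank_test(times1, events1, times2, events2) -> TestResult:
    """Two-group log-rank test (observed minus expected, chi-square df=1).

    ``direction`` of the result is "up" when group 1 has more events than
    expected (worse survival in group 1), "down" when fewer.
    """
    t1 = np.asarray(times1, dtype=float)
    t2 = np.asarray(times2, dtype=float)
    e1 = np.asarray(events1, dtype=bool)
    e2 = np.asarray(events2, dtype=bool)
    if t1.size == 0 or t2.size == 0:
        raise ValidationError("log-rank test requires both groups non-empty")
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group1 = np.concatenate([np.ones(t1.size, bool), np.zeros(t2.size, bool)])

    event_times = np.unique(times[events])
    if event_times.size == 0:
        return TestResult(unit_id="logrank", statistic=0.0, p_value=1.0)

    o_minus_e = 0.0
    var = 0.0
    for tau in event_times:
        at_risk = times >= tau
        n = at_risk.sum()
        n1 = (at_risk & group1).sum()
        dying = (times == tau) & events
        d = dying.sum()
        d1 = (dying & group1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return TestResult(unit_id="logrank", statistic=0.0, p_value=1.0)
    stat = o_minus_e**2 / var
    p = float(scipy.stats.chi2.sf(stat, df=1))
    direction = "up" if o_minus_e > 0 else ("down" if o_minus_e < 0 else "none")
    return TestResult(
        unit_id="logrank", statistic=float(stat), p_value=p, direction=direction
    )
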