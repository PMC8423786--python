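"""Bulk-cohort association of gene signatures with outcome and age.

The central operation is the optimal-cutpoint survival scan: a per-sample
signature score (mean z-scored expression over the signature's genes) is
thresholded at every admissible cutpoint between consecutive distinct
scores, a two-group log-rank test is evaluated at each, and the cutpoint
minimizing the raw p-value is reported.  Because the minimum over
cutpoints is anti-conservative, the raw p is always accompanied by a
Bonferroni adjustment whose family is the tested cutpoints times the
signatures tested in one invocation.

Per-gene screens produce labeled gene lists (up in a risk group, directly
or inversely age-correlated, worse or better survival with high
expression) that cluster signatures can then be tested against with
one-sided Fisher enrichment.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import (
    GeneSet,
    NormalizedMatrix,
    TestResult,
    ValidationError,
)
from .enrichment import EnrichmentResult, external_set_enrichment
from .stats import bh_adjust, logrank_test  # noqa: F401

__all__ = [
    "SurvivalCurve",
    "ScanResult",
    "signature_zscore_average",
    "km_estimate",
    "logrank_test",
    "kaplan_scan",
    "scan_signatures",
    "per_gene_group_differential",
    "per_gene_age_correlation",
    "per_gene_survival_groups",
    "signature_label_enrichment",
]

#: signatures feeding the survival scan must have more than two genes
MIN_SCAN_SIGNATURE_SIZE = 3


@dataclass
class SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimate at the observed event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def probability_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class ScanResult:
    signature: str
    cutpoint: float
    n_low: int
    n_high: int
    n_cutpoints: int
    statistic: float
    p_value: float
    adjusted_p: float
    worse_group: str  # "high-score" or "low-score"
    correction: str = "Bonferroni"


def signature_zscore_average(
    bulk_matrix: NormalizedMatrix, gene_set: GeneSet, for_scan: bool = True
) -> pd.Series:
    """Per-sample mean z-scored expression over the signature's genes.

    Each gene is standardized across samples; a sample's score is the mean
    z over the signature genes present in the matrix.  Constant genes have
    no defined z and are excluded with a warning.  When the score feeds
    the survival scan, signatures with fewer than three usable genes are
    rejected (sets of two or fewer genes are not scanned).
    """
    gidx = bulk_matrix.gene_index()
    present = sorted(g for g in gene_set.genes if g in gidx)
    if not present:
        raise ValidationError(
            f"signature {gene_set.name!r} shares no genes with the bulk matrix"
        )
    rows = bulk_matrix.values[[gidx[g] for g in present], :]
    sd = rows.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant genes from the z-score "
            f"of {gene_set.name!r}",
            stacklevel=2,
        )
        rows, sd = rows[~constant], sd[~constant]
    if rows.shape[0] == 0:
        raise ValidationError(f"no gene of {gene_set.name!r} varies across samples")
    if for_scan and rows.shape[0] < MIN_SCAN_SIGNATURE_SIZE:
        raise ValidationError(
            f"signature {gene_set.name!r} has {rows.shape[0]} usable genes; "
            f"the survival scan requires more than two"
        )
    z = (rows - rows.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.Series(z.mean(axis=0), index=bulk_matrix.cell_ids, name=gene_set.name)


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator with right censoring."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if np.any(t < 0):
        raise ValidationError("survival times must be >= 0")
    event_times = np.unique(t[e])
    at_risk = np.array([(t >= tau).sum() for tau in event_times], dtype=np.int64)
    deaths = np.array([((t == tau) & e).sum() for tau in event_times], dtype=np.int64)
    with np.errstate(invalid="ignore"):
        survival = np.cumprod(1.0 - deaths / at_risk)
    return SurvivalCurve(event_times=event_times, at_risk=at_risk, survival=survival)


def _logrank_all_cutpoints(
    scores: np.ndarray, times: np.ndarray, events: np.ndarray, valid_k: np.ndarray
):
    """Log-rank statistic at every candidate split of the score order.

    ``valid_k`` lists low-group sizes k; the low group is the k samples
    with the smallest scores.  Returns (statistic, p, o_minus_e) arrays
    aligned to ``valid_k``, where o_minus_e is observed-minus-expected
    events in the low group.
    """
    order = np.argsort(scores, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    event_times = np.unique(t_sorted[e_sorted])
    m = event_times.size
    if m == 0:
        zeros = np.zeros(valid_k.size)
        return zeros, np.ones(valid_k.size), zeros
    at_risk_mat = t_sorted[:, None] >= event_times[None, :]  # n x m
    death_mat = (t_sorted[:, None] == event_times[None, :]) & e_sorted[:, None]
    n_j = at_risk_mat.sum(axis=0).astype(float)
    d_j = death_mat.sum(axis=0).astype(float)
    n1 = np.cumsum(at_risk_mat, axis=0)[valid_k - 1, :].astype(float)
    d1 = np.cumsum(death_mat, axis=0)[valid_k - 1, :].astype(float)
    frac = n1 / n_j
    o_minus_e = (d1 - d_j * frac).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_j = d_j * frac * (1 - frac) * (n_j - d_j) / (n_j - 1)
    var = np.where(n_j > 1, var_j, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(var > 0, o_minus_e**2 / var, 0.0)
    p = np.where(var > 0, scipy.stats.chi2.sf(stat, df=1), 1.0)
    return stat, p, o_minus_e


def _candidate_splits(
    scores_sorted: np.ndarray, min_group_fraction: float
) -> np.ndarray:
    n = scores_sorted.size
    g_min = max(MIN_SCAN_SIGNATURE_SIZE, math.ceil(min_group_fraction * n))
    ks = np.arange(1, n)
    distinct = scores_sorted[:-1] < scores_sorted[1:]
    ok = distinct & (ks >= g_min) & (n - ks >= g_min)
    return ks[ok]


def kaplan_scan(
    scores,
    times,
    events,
    min_group_fraction: float = 0.1,
    signature: str = "signature",
    family_size: int = 1,
) -> ScanResult:
    """Optimal-cutpoint log-rank scan over a per-sample score.

    Cutpoints are the midpoints between consecutive distinct sorted
    scores; splits leaving either group below max(3, ceil(fraction * n))
    samples are skipped.  Samples scoring exactly at the cutpoint fall in
    the low group.  The reported p is the scan minimum (raw); the
    Bonferroni-adjusted p multiplies it by the number of cutpoints tested
    and by ``family_size`` (the signatures scanned in one invocation), so
    the adjusted value is calibrated despite the scan optimism.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if scores.std() == 0:
        raise ValidationError("all scores equal: no cutpoint to scan")
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    valid_k = _candidate_splits(s_sorted, min_group_fraction)
    if valid_k.size == 0:
        raise ValidationError(
            "no admissible cutpoint under the minimum group size constraint"
        )
    stat, p, o_minus_e = _logrank_all_cutpoints(scores, times, events, valid_k)
    best = int(np.argmin(p))  # ties: smallest cutpoint wins
    k = int(valid_k[best])
    cut = float((s_sorted[k - 1] + s_sorted[k]) / 2.0)
    worse = "low-score" if o_minus_e[best] > 0 else "high-score"
    raw = float(p[best])
    return ScanResult(
        signature=signature,
        cutpoint=cut,
        n_low=k,
        n_high=int(scores.size - k),
        n_cutpoints=int(valid_k.size),
        statistic=float(stat[best]),
        p_value=raw,
        adjusted_p=min(raw * valid_k.size * family_size, 1.0),
        worse_group=worse,
    )


def scan_signatures(
    bulk_matrix: NormalizedMatrix,
    times,
    events,
    signatures: list[GeneSet],
    min_group_fraction: float = 0.1,
) -> list[ScanResult]:
    """Scan each signature's z-score average, Bonferroni-corrected across
    the signatures tested in this invocation.  Signatures too small to
    scan are skipped with a warning."""
    usable: list[tuple[GeneSet, pd.Series]] = []
    for gs in signatures:
        try:
            usable.append((gs, signature_zscore_average(bulk_matrix, gs)))
        except ValidationError as exc:
            warnings.warn(f"skipping {gs.name!r}: {exc}", stacklevel=2)
    return [
        kaplan_scan(
            score.to_numpy(),
            times,
            events,
            min_group_fraction,
            signature=gs.name,
            family_size=len(usable),
        )
        for gs, score in usable
    ]


def per_gene_group_differential(
    bulk_rpm: NormalizedMatrix,
    group_labels,
    fdr: float = 0.01,
    pseudocount: float = 1.0,
) -> tuple[dict[str, list[str]], list[TestResult]]:
    """Per-gene one-way ANOVA on log2(RPM + pseudocount) between groups.

    Returns (lists, results): ``lists`` maps each group label to the
    significant genes (BH q < ``fdr``) whose mean is highest in that
    group; ``results`` holds every gene's F statistic, p and q.
    Zero-variance genes get p = 1 by convention.
    """
    groups = np.asarray(group_labels)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    for lvl in levels:
        if (groups == lvl).sum() < 2:
            raise ValidationError(f"group {lvl!r} has fewer than 2 samples")
    log_expr = np.log2(bulk_rpm.values + pseudocount)
    blocks = [log_expr[:, groups == lvl] for lvl in levels]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p = scipy.stats.f_oneway(*blocks, axis=1)
    flat = log_expr.var(axis=1) == 0
    f_stat = np.where(flat, 0.0, f_stat)
    p = np.where(flat | ~np.isfinite(p), 1.0, p)
    q = bh_adjust(p)
    group_means = np.stack([b.mean(axis=1) for b in blocks], axis=1)
    top_group = np.asarray(levels)[group_means.argmax(axis=1)]
    lists: dict[str, list[str]] = {lvl: [] for lvl in levels}
    results: list[TestResult] = []
    for i, gene in enumerate(bulk_rpm.gene_ids):
        results.append(
            TestResult(
                unit_id=gene,
                statistic=float(f_stat[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                direction="up" if q[i] < fdr else "none",
            )
        )
        if q[i] < fdr:
            lists[str(top_group[i])].append(gene)
    return lists, results


def per_gene_age_correlation(
    bulk_matrix: NormalizedMatrix, ages, fdr: float = 0.01
) -> tuple[dict[str, list[str]], list[TestResult]]:
    """Per-gene Pearson correlation between expression and age at diagnosis.

    Significant genes (BH q < ``fdr``) are split into ``age_direct``
    (r > 0) and ``age_inverse`` (r < 0) lists.  Constant genes are
    excluded with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 3:
        raise ValidationError("age correlation needs at least 3 samples")
    if ages.std() == 0:
        raise ValidationError("age has zero variance")
    expr = bulk_matrix.values
    keep = expr.std(axis=1) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant genes from age correlation",
            stacklevel=2,
        )
    genes = [g for g, k in zip(bulk_matrix.gene_ids, keep) if k]
    x = expr[keep]
    xc = x - x.mean(axis=1, keepdims=True)
    ac = ages - ages.mean()
    r = (xc @ ac) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(ac))
    r = np.clip(r, -1.0, 1.0)
    n = ages.size
    with np.errstate(divide="ignore"):
        t_stat = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * scipy.stats.t.sf(np.abs(t_stat), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    q = bh_adjust(p)
    lists: dict[str, list[str]] = {"age_direct": [], "age_inverse": []}
    results = []
    for gene, ri, pi, qi in zip(genes, r, p, q):
        sig = qi < fdr
        results.append(
            TestResult(
                unit_id=gene,
                statistic=float(ri),
                p_value=float(pi),
                q_value=float(qi),
                direction=("up" if ri > 0 else "down") if sig else "none",
            )
        )
        if sig:
            lists["age_direct" if ri > 0 else "age_inverse"].append(gene)
    return lists, results


def per_gene_survival_groups(
    bulk_matrix: NormalizedMatrix,
    times,
    events,
    fdr: float = 0.01,
    min_group_fraction: float = 0.1,
) -> tuple[dict[str, list[str]], list[TestResult]]:
    """Optimal-cutpoint scan per gene; BH over genes.

    Each gene's p entering the BH family is its scan minimum multiplied
    by the number of cutpoints tested (clipped at 1), so the per-gene
    values are calibrated before the across-gene correction.  Significant
    genes (BH q < ``fdr``) are split into ``surv_worse`` (high expression
    in the worse-survival group) and ``surv_better``.  Genes that cannot
    be scanned (constant expression, no admissible cutpoint) are skipped
    with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    genes: list[str] = []
    raw_p: list[float] = []
    stats: list[float] = []
    worse_high: list[bool] = []
    n_skipped = 0
    for i, gene in enumerate(bulk_matrix.gene_ids):
        expr = bulk_matrix.values[i]
        if expr.std() == 0:
            n_skipped += 1
            continue
        order = np.argsort(expr, kind="stable")
        valid_k = _candidate_splits(expr[order], min_group_fraction)
        if valid_k.size == 0:
            n_skipped += 1
            continue
        stat, p, o_minus_e = _logrank_all_cutpoints(expr, times, events, valid_k)
        best = int(np.argmin(p))
        genes.append(gene)
        raw_p.append(min(float(p[best]) * valid_k.size, 1.0))
        stats.append(float(stat[best]))
        worse_high.append(o_minus_e[best] <= 0)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} unscannable genes", stacklevel=2)
    q = bh_adjust(raw_p) if genes else np.empty(0)
    lists: dict[str, list[str]] = {"surv_worse": [], "surv_better": []}
    results = []
    for gene, pi, si, wh, qi in zip(genes, raw_p, stats, worse_high, q):
        sig = qi < fdr
        results.append(
            TestResult(
                unit_id=gene,
                statistic=si,
                p_value=pi,
                q_value=float(qi),
                direction=("up" if wh else "down") if sig else "none",
            )
        )
        if sig:
            lists["surv_worse" if wh else "surv_better"].append(gene)
    return lists, results


def signature_label_enrichment(
    cluster_signatures: list[GeneSet],
    labeled_gene_lists: dict[str, GeneSet],
    universe,
    fdr: float = 0.01,
) -> dict[str, dict[str, EnrichmentResult]]:
    """Enrichment of each cluster signature in each labeled gene list
    (risk-up, age-direct/inverse, worse/better survival).

    Returns a cluster x label grid of enrichment results; BH spans the
    label lists within each signature.
    """
    grid: dict[str, dict[str, EnrichmentResult]] = {}
    labels = list(labeled_gene_lists)
    refs = [labeled_gene_lists[lbl] for lbl in labels]
    for sig in cluster_signatures:
        per_sig = external_set_enrichment(sig, refs, universe, fdr=fdr)
        grid[sig.name] = {lbl: res for lbl, res in zip(labels, per_sig)}
    return grid
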