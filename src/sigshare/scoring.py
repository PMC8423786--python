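"""Per-cell signature scoring, cluster-composition tests, and deconvolution
expected-cell counts.

The signature score of a cell is the mean of (cp10k + 1) over a reference
gene set minus the same mean over n randomly drawn background genes, with
n = max(#reference, 50).  The background is drawn once per scoring call,
uniformly without replacement from the non-reference genes, from a seeded
generator (an expression-binned scheme is available via
``scheme="binned"``).  The score is computed on linear cp10k values, not
the log transform used for display.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .datatypes import (
    ClinicalTable,
    ClusterAssignment,
    GeneSet,
    NormalizedMatrix,
    TestResult,
    ValidationError,
)
from .stats import bh_adjust, chi_square_yates_2x2  # noqa: F401

__all__ = [
    "ScoreConfig",
    "ScoreResult",
    "signature_score",
    "chi_square_yates_2x2",
    "composition_test",
    "rxc_composition_test",
    "ls_deconvolve",
    "DeconvExpectation",
    "expected_cells_from_deconvolution",
]

BACKGROUND_FLOOR = 50


@dataclass
class ScoreConfig:
    """Background-draw settings for the signature score.

    ``background_floor`` is the minimum background size n0; the draw uses
    n = max(#reference, n0).  ``scheme`` is "uniform" (default) or
    "binned" (background matched to the reference's expression deciles).
    """

    background_floor: int = BACKGROUND_FLOOR
    seed: int = 0
    scheme: str = "uniform"

    def background_size(self, n_reference: int) -> int:
        return max(n_reference, self.background_floor)


@dataclass
class ScoreResult:
    cell_ids: list[str]
    scores: np.ndarray
    reference_genes: frozenset[str]
    background_genes: frozenset[str]

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.cell_ids, name="signature_score")


def _draw_background(
    matrix: NormalizedMatrix,
    reference_idx: np.ndarray,
    n_background: int,
    config: ScoreConfig,
) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    candidates = np.setdiff1d(np.arange(matrix.n_genes), reference_idx)
    if candidates.size < n_background:
        raise ValidationError(
            f"only {candidates.size} candidate background genes for a draw of "
            f"{n_background}"
        )
    if config.scheme == "uniform":
        return rng.choice(candidates, size=n_background, replace=False)
    if config.scheme == "binned":
        # match background to the reference genes' mean-expression deciles
        means = matrix.values.mean(axis=1)
        edges = np.quantile(means, np.linspace(0, 1, 11))
        edges[0], edges[-1] = -np.inf, np.inf
        ref_bins = np.digitize(means[reference_idx], edges[1:-1])
        cand_bins = np.digitize(means[candidates], edges[1:-1])
        per_bin = np.bincount(ref_bins, minlength=10).astype(float)
        want = np.round(per_bin / per_bin.sum() * n_background).astype(int)
        while want.sum() < n_background:
            want[np.argmax(per_bin)] += 1
        picked: list[np.ndarray] = []
        for b in range(10):
            pool = candidates[cand_bins == b]
            k = min(want[b], pool.size)
            if k:
                picked.append(rng.choice(pool, size=k, replace=False))
        chosen = np.concatenate(picked) if picked else np.empty(0, int)
        if chosen.size < n_background:  # top up from remaining candidates
            rest = np.setdiff1d(candidates, chosen)
            chosen = np.concatenate(
                [chosen, rng.choice(rest, size=n_background - chosen.size, replace=False)]
            )
        return chosen
    raise ValidationError(f"unknown background scheme {config.scheme!r}")


def signature_score(
    norm_matrix: NormalizedMatrix,
    reference: GeneSet,
    config: ScoreConfig | None = None,
) -> ScoreResult:
    """Per-cell signature score against a seeded random background.

    score(cell) = mean over reference genes of (cp10k + 1)
                - mean over n background genes of (cp10k + 1),
    n = max(#reference, background_floor).  Requires a cp10k (linear)
    matrix.
    """
    config = config or ScoreConfig()
    if norm_matrix.transform_tag != "cp10k":
        raise ValidationError(
            "signature_score requires a linear cp10k matrix, got "
            f"{norm_matrix.transform_tag!r}"
        )
    if len(reference) == 0:
        raise ValidationError("empty reference gene set")
    gidx = norm_matrix.gene_index()
    missing = [g for g in reference.genes if g not in gidx]
    if missing:
        raise ValidationError(f"reference genes absent from matrix: {missing[:5]}")
    ref_idx = np.array(sorted(gidx[g] for g in reference.genes))
    n_bg = config.background_size(ref_idx.size)
    bg_idx = _draw_background(norm_matrix, ref_idx, n_bg, config)
    ref_mean = (norm_matrix.values[ref_idx, :] + 1.0).mean(axis=0)
    bg_mean = (norm_matrix.values[bg_idx, :] + 1.0).mean(axis=0)
    return ScoreResult(
        cell_ids=list(norm_matrix.cell_ids),
        scores=ref_mean - bg_mean,
        reference_genes=frozenset(reference.genes),
        background_genes=frozenset(norm_matrix.gene_ids[i] for i in bg_idx),
    )


def composition_test(
    assignment: ClusterAssignment, fdr: float = 0.01
) -> list[TestResult]:
    """Per-(cluster, group) 2x2 over/under-representation tests.

    For each cluster and each sample-group label a 2x2 table
    {in cluster, not} x {in group, not} is tested with the
    Yates-corrected chi-square; BH spans all tested pairs.  Pairs with a
    degenerate margin are skipped with a warning.  ``direction`` is "up"
    for over- and "down" for under-representation; significance is
    q < ``fdr``.
    """
    clusters = np.asarray(assignment.cluster_labels)
    groups = assignment.group_labels()
    group_levels = sorted(set(groups))
    if len(group_levels) < 2:
        raise ValidationError("composition test needs at least 2 groups")
    units: list[tuple[str, str, float, float, str]] = []
    n = clusters.size
    for cl in assignment.clusters():
        in_cl = clusters == cl
        for grp in group_levels:
            in_grp = groups == grp
            a = int((in_cl & in_grp).sum())
            b = int((in_cl & ~in_grp).sum())
            c = int((~in_cl & in_grp).sum())
            d = n - a - b - c
            try:
                res = chi_square_yates_2x2([[a, b], [c, d]])
            except ValidationError as exc:
                warnings.warn(
                    f"skipping cluster {cl!r} x group {grp!r}: {exc}", stacklevel=2
                )
                continue
            expected = (a + b) * (a + c) / n
            direction = "up" if a > expected else ("down" if a < expected else "none")
            units.append((cl, grp, res.statistic, res.p_value, direction))
    qs = bh_adjust([u[3] for u in units]) if units else np.empty(0)
    return [
        TestResult(
            unit_id=f"{cl}|{grp}",
            statistic=stat,
            p_value=p,
            q_value=float(q),
            direction=direction if q < fdr else "none",
        )
        for (cl, grp, stat, p, direction), q in zip(units, qs)
    ]


def rxc_composition_test(assignment: ClusterAssignment) -> TestResult:
    """Single R x C chi-square over the full cluster-by-group table
    (variant; the per-pair 2x2 form is the default analysis)."""
    table = pd.crosstab(
        np.asarray(assignment.cluster_labels), assignment.group_labels()
    ).to_numpy()
    stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return TestResult(unit_id="rxc", statistic=float(stat), p_value=float(p))


def ls_deconvolve(
    bulk_profile: np.ndarray, cluster_reference_profiles: pd.DataFrame
) -> pd.Series:
    """Non-negative least-squares estimate of per-cluster proportions.

    ``cluster_reference_profiles`` is genes x clusters of per-cluster mean
    cp10k.  This is a plain NNLS decomposition (proportions renormalized
    to sum to 1), not a re-implementation of any published reference-based
    decomposition model; externally computed proportion tables can be fed
    straight into :func:`expected_cells_from_deconvolution`.
    """
    refs = cluster_reference_profiles.to_numpy(dtype=float)
    y = np.asarray(bulk_profile, dtype=float)
    if y.shape[0] != refs.shape[0]:
        raise ValidationError("bulk profile and references need a shared gene space")
    if refs.shape[1] > 1:
        rank = np.linalg.matrix_rank(refs)
        if rank < refs.shape[1]:
            warnings.warn(
                "reference profiles are rank-deficient; proportions are an "
                "ambiguous fit",
                stacklevel=2,
            )
    coef, _ = scipy.optimize.nnls(refs, y)
    total = coef.sum()
    if total == 0:
        coef = np.full(refs.shape[1], 1.0 / refs.shape[1])
    else:
        coef = coef / total
    return pd.Series(coef, index=cluster_reference_profiles.columns, name="proportion")


@dataclass
class DeconvExpectation:
    """Expected proportional cell counts per risk group and cluster.

    For each risk group: c = avg_nuclei(group) x n_bulk_samples(group);
    expected count of a cluster = c x mean predicted cluster percentage
    over the group's bulk samples.
    """

    per_group: pd.DataFrame  # index group; columns avg_nuclei, n_bulk_samples, c
    expected_counts: pd.DataFrame  # index group; columns clusters
    tests: list[TestResult] = field(default_factory=list)


def expected_cells_from_deconvolution(
    proportions: pd.DataFrame,
    clinical: ClinicalTable,
    avg_nuclei_per_group: dict[str, float],
    fdr: float = 0.01,
) -> DeconvExpectation:
    """Expected cells per cluster in each risk group, with composition tests.

    ``proportions`` is samples x clusters of predicted cluster fractions.
    Each bulk sample's risk group comes from ``clinical``;
    ``avg_nuclei_per_group`` gives the mean high-quality nuclei per
    single-nucleus sample in that group.  Significance of group-wise
    differences in the expected composition is assessed per
    (cluster, group) with 2x2 Yates chi-squares (group vs rest) on the
    rounded expected counts, BH-corrected.
    """
    clin = clinical.frame.set_index("sample_id")
    missing = [s for s in proportions.index if s not in clin.index]
    if missing:
        raise ValidationError(f"bulk samples without clinical row: {missing[:5]}")
    groups = clin.loc[proportions.index, "risk_group"]
    rows = []
    counts = {}
    for grp, sub in proportions.groupby(groups):
        if grp not in avg_nuclei_per_group:
            raise ValidationError(f"no average nuclei count for risk group {grp!r}")
        c = avg_nuclei_per_group[grp] * len(sub)
        rows.append((grp, avg_nuclei_per_group[grp], len(sub), c))
        counts[grp] = sub.mean(axis=0) * c
    per_group = pd.DataFrame(
        rows, columns=["risk_group", "avg_nuclei", "n_bulk_samples", "c"]
    ).set_index("risk_group")
    expected = pd.DataFrame(counts).T

    rounded = expected.round().astype(int)
    units = []
    for cl in rounded.columns:
        for grp in rounded.index:
            a = int(rounded.loc[grp, cl])
            b = int(rounded.loc[grp].sum() - a)
            c2 = int(rounded[cl].sum() - a)
            d = int(rounded.values.sum() - a - b - c2)
            try:
                res = chi_square_yates_2x2([[a, b], [c2, d]])
            except ValidationError:
                continue
            n_tot = a + b + c2 + d
            exp_a = (a + b) * (a + c2) / n_tot
            units.append(
                (f"{cl}|{grp}", res.statistic, res.p_value,
                 "up" if a > exp_a else ("down" if a < exp_a else "none"))
            )
    qs = bh_adjust([u[2] for u in units]) if units else np.empty(0)
    tests = [
        TestResult(unit_id=uid, statistic=stat, p_value=p, q_value=float(q),
                   direction=direction if q < fdr else "none")
        for (uid, stat, p, direction), q in zip(units, qs)
    ]
    return DeconvExpectation(per_group=per_group, expected_counts=expected, tests=tests)
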