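"""Cell/gene quality control, normalization, and cluster marker definitions.

Two marker definitions are implemented for each cluster:

* the **upregulated set A** — genes whose mean expression in the cluster
  is significantly higher than the mean over all other cells pooled; and
* the **specific signature B** — genes whose cluster mean is significantly
  higher than *each and every* other cluster's mean individually.

Significance uses Welch's t-test with Benjamini-Hochberg correction at an
FDR threshold of 0.01 by default.  For A the BH family is all genes tested
for the cluster; for B, BH is applied across all genes within each
pairwise cluster comparison and a gene must pass in every comparison (a
global-family variant is available via ``bh_family="global"``).

Tests run on a normalized matrix; the default pipeline transform is
log1p of counts-per-10,000, but externally standardized magnitudes are
accepted unchanged (``transform_tag="standardized"``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    ClusterAssignment,
    ExpressionMatrix,
    NormalizedMatrix,
    TestResult,
    ValidationError,
)
from .stats import bh_adjust, welch_t_from_moments, welch_t_test  # noqa: F401

__all__ = [
    "DETECTED_GENE_BOUNDS",
    "SignatureSet",
    "filter_cells_by_detected_genes",
    "filter_genes_by_cells",
    "cp10k_normalize",
    "welch_t_test",
    "bh_adjust",
    "upregulated_genes",
    "specific_signature",
    "signatures_for_all_clusters",
]

#: detected-gene QC bounds per tissue preset (min, max), inclusive
DETECTED_GENE_BOUNDS: dict[str, tuple[int, int]] = {
    "human_adrenal": (3000, 9000),
    "neuroblastoma": (2000, 8000),
    "mouse_adrenal": (2000, 8000),
}


@dataclass
class SignatureSet:
    """Marker sets for one cluster with their test statistics.

    ``upregulated_A`` maps gene -> TestResult of the one-vs-pooled-rest
    test.  ``specific_B`` maps gene -> {other_cluster -> TestResult} with
    one significant pairwise result per other cluster.  B is not a subset
    of A by construction: the two definitions use different test families.
    """

    cluster_label: str
    upregulated_A: dict[str, TestResult] = field(default_factory=dict)
    specific_B: dict[str, dict[str, TestResult]] = field(default_factory=dict)

    @property
    def genes_A(self) -> frozenset[str]:
        return frozenset(self.upregulated_A)

    @property
    def genes_B(self) -> frozenset[str]:
        return frozenset(self.specific_B)


def filter_cells_by_detected_genes(
    matrix: ExpressionMatrix,
    min_genes: int | None = None,
    max_genes: int | None = None,
    preset: str | None = None,
) -> ExpressionMatrix:
    """Keep cells whose detected-gene count lies in [min_genes, max_genes].

    A gene is detected in a cell when its count is > 0.  Both bounds are
    inclusive.  ``preset`` looks bounds up in :data:`DETECTED_GENE_BOUNDS`.
    """
    if preset is not None:
        if preset not in DETECTED_GENE_BOUNDS:
            raise ValidationError(
                f"unknown preset {preset!r}; options: {sorted(DETECTED_GENE_BOUNDS)}"
            )
        min_genes, max_genes = DETECTED_GENE_BOUNDS[preset]
    if min_genes is None or max_genes is None:
        raise ValidationError("provide min_genes and max_genes, or a preset")
    if min_genes > max_genes:
        raise ValidationError("min_genes must be <= max_genes")
    detected = (matrix.counts > 0).sum(axis=0)
    keep = (detected >= min_genes) & (detected <= max_genes)
    if not keep.any():
        warnings.warn("detected-gene filter removed every cell", stacklevel=2)
    return matrix.subset_cells(keep)


def filter_genes_by_cells(
    matrix: ExpressionMatrix, min_cells: int = 5, strict: bool = True
) -> ExpressionMatrix:
    """Keep genes expressed (count > 0) in more than ``min_cells`` cells.

    With ``strict`` (default) the comparison is ``> min_cells``, so a gene
    present in exactly ``min_cells`` cells is removed; ``strict=False``
    keeps it.
    """
    if min_cells < 0:
        raise ValidationError("min_cells must be >= 0")
    n_expressing = (matrix.counts > 0).sum(axis=1)
    keep = n_expressing > min_cells if strict else n_expressing >= min_cells
    return matrix.subset_genes(keep)


def cp10k_normalize(
    matrix: ExpressionMatrix, log_transform: bool = False
) -> NormalizedMatrix:
    """Scale each cell to 10,000 total counts; optionally log1p-transform.

    Cells with zero total counts cannot be scaled; they are dropped with a
    warning.
    """
    totals = matrix.counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        dropped = [matrix.cell_ids[i] for i in np.flatnonzero(zero)]
        warnings.warn(
            f"excluding {len(dropped)} zero-count cells from normalization: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
        matrix = matrix.subset_cells(~zero)
        totals = totals[~zero]
    values = matrix.counts * (10_000.0 / totals)
    tag = "cp10k"
    if log_transform:
        values = np.log1p(values)
        tag = "log1p_cp10k"
    return NormalizedMatrix(
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
        values=values,
        transform_tag=tag,
        dataset_id=matrix.dataset_id,
    )


def _cluster_moments(values: np.ndarray, member: np.ndarray):
    """Per-gene mean and ddof=1 variance over a boolean cell mask."""
    n = int(member.sum())
    sub = values[:, member]
    return sub.mean(axis=1), sub.var(axis=1, ddof=1), n


def _check_cluster_sizes(labels: np.ndarray, cluster: str) -> None:
    uniq, counts = np.unique(labels, return_counts=True)
    if cluster not in uniq:
        raise ValidationError(f"cluster {cluster!r} has no cells")
    if uniq.size < 2:
        raise ValidationError("marker detection needs at least two clusters")
    sizes = dict(zip(uniq.tolist(), counts.tolist()))
    small = [c for c, s in sizes.items() if s < 2]
    if small:
        raise ValidationError(f"clusters with fewer than 2 cells: {small}")


def upregulated_genes(
    norm_matrix: NormalizedMatrix,
    assignment: ClusterAssignment,
    cluster: str,
    fdr: float = 0.01,
) -> dict[str, TestResult]:
    """Definition A: genes significantly higher in the cluster than in the
    pooled complement (all other cells), at BH FDR < ``fdr``.

    Strictly higher means are required; exact ties fail.  The BH family is
    every gene in the matrix.
    """
    labels = assignment.labels_for(norm_matrix.cell_ids)
    _check_cluster_sizes(labels, cluster)
    member = labels == cluster
    m1, v1, n1 = _cluster_moments(norm_matrix.values, member)
    m2, v2, n2 = _cluster_moments(norm_matrix.values, ~member)
    t, p = welch_t_from_moments(m1, v1, n1, m2, v2, n2)
    q = bh_adjust(p)
    out: dict[str, TestResult] = {}
    for i, gene in enumerate(norm_matrix.gene_ids):
        if m1[i] > m2[i] and q[i] < fdr:
            out[gene] = TestResult(
                unit_id=gene,
                statistic=float(t[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                direction="up",
            )
    return out


def specific_signature(
    norm_matrix: NormalizedMatrix,
    assignment: ClusterAssignment,
    cluster: str,
    fdr: float = 0.01,
    bh_family: str = "per_comparison",
) -> dict[str, dict[str, TestResult]]:
    """Definition B: genes significantly higher in the cluster than each
    and every other cluster individually.

    For every other cluster k a pairwise Welch test is run per gene.  With
    ``bh_family="per_comparison"`` (default) BH spans all genes within
    each pairwise comparison; ``"global"`` pools every (gene, comparison)
    p-value into one family.  A gene belongs to B iff, in each comparison,
    its cluster mean is strictly higher and the adjusted p is below
    ``fdr``.
    """
    if bh_family not in ("per_comparison", "global"):
        raise ValidationError(f"unknown bh_family {bh_family!r}")
    labels = assignment.labels_for(norm_matrix.cell_ids)
    _check_cluster_sizes(labels, cluster)
    others = [c for c in assignment.clusters() if c != cluster and c in labels]
    member = labels == cluster
    m1, v1, n1 = _cluster_moments(norm_matrix.values, member)

    per_comp: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for other in others:
        m2, v2, n2 = _cluster_moments(norm_matrix.values, labels == other)
        t, p = welch_t_from_moments(m1, v1, n1, m2, v2, n2)
        per_comp[other] = (t, p, m1 > m2, np.empty(0))

    if bh_family == "per_comparison":
        for other, (t, p, higher, _) in per_comp.items():
            per_comp[other] = (t, p, higher, bh_adjust(p))
    else:
        pooled = np.concatenate([per_comp[o][1] for o in others])
        q_all = bh_adjust(pooled).reshape(len(others), -1)
        for j, other in enumerate(others):
            t, p, higher, _ = per_comp[other]
            per_comp[other] = (t, p, higher, q_all[j])

    result: dict[str, dict[str, TestResult]] = {}
    for i, gene in enumerate(norm_matrix.gene_ids):
        passed: dict[str, TestResult] = {}
        for other in others:
            t, p, higher, q = per_comp[other]
            if not (higher[i] and q[i] < fdr):
                break
            passed[other] = TestResult(
                unit_id=gene,
                statistic=float(t[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                direction="up",
            )
        else:
            result[gene] = passed
    return result


def signatures_for_all_clusters(
    norm_matrix: NormalizedMatrix,
    assignment: ClusterAssignment,
    fdr: float = 0.01,
    bh_family: str = "per_comparison",
) -> dict[str, SignatureSet]:
    """Both marker definitions for every cluster in the assignment."""
    out: dict[str, SignatureSet] = {}
    for cluster in assignment.clusters():
        out[cluster] = SignatureSet(
            cluster_label=cluster,
            upregulated_A=upregulated_genes(norm_matrix, assignment, cluster, fdr),
            specific_B=specific_signature(
                norm_matrix, assignment, cluster, fdr, bh_family
            ),
        )
    return out
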