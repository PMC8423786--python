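"""Transcriptome-level similarity of cell populations.

Cluster-average expression profiles (possibly spanning two datasets after
ortholog restriction) are quantile-normalized, compared by Euclidean
distance, and agglomerated with the Ward-2 criterion.  Branch confidence
comes from a multiscale bootstrap over genes: ordinary bootstrap
probabilities (BP) at unit scale, and approximately unbiased (AU)
p-values from a weighted least-squares fit of the per-scale normal
quantiles against (sqrt(r), 1/sqrt(r)).  AU > 95% marks a strongly
supported split.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats

from .datatypes import ClusterAssignment, NormalizedMatrix, ValidationError

__all__ = [
    "ClusterProfileMatrix",
    "SupportedDendrogram",
    "cluster_average_profiles",
    "quantile_normalize",
    "euclidean_distance_matrix",
    "ward2_linkage",
    "clades_from_linkage",
    "bootstrap_branch_support",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))
HIGH_SUPPORT_AU = 95.0


@dataclass
class ClusterProfileMatrix:
    """Genes x clusters matrix of average expression with provenance tags."""

    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def clusters(self) -> list[str]:
        return self.frame.columns.tolist()

    @property
    def n_genes(self) -> int:
        return len(self.frame)


@dataclass
class SupportedDendrogram:
    """Ward merge tree with per-branch bootstrap support.

    ``linkage`` follows the scipy convention (rows: idx1, idx2, height,
    size).  ``bp`` and ``au`` are percentages aligned to the linkage rows
    (internal nodes in merge order).
    """

    labels: list[str]
    linkage: np.ndarray
    bp: np.ndarray
    au: np.ndarray

    def branch_table(self) -> pd.DataFrame:
        clades = clades_from_linkage(self.linkage, self.labels)
        return pd.DataFrame(
            {
                "clade": ["|".join(sorted(c)) for c in clades],
                "height": self.linkage[:, 2],
                "bp": self.bp,
                "au": self.au,
                "high_support": self.au > HIGH_SUPPORT_AU,
            }
        )

    def to_newick(self) -> str:
        """Newick string with AU/BP percentages as branch comments."""
        n = len(self.labels)

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            row = node - n
            left = render(int(self.linkage[row, 0]))
            right = render(int(self.linkage[row, 1]))
            h = self.linkage[row, 2]
            return f"({left},{right})[au={self.au[row]:.1f},bp={self.bp[row]:.1f}]:{h:.6g}"

        return render(2 * n - 2) + ";"


def cluster_average_profiles(
    norm_matrix: NormalizedMatrix,
    assignment: ClusterAssignment,
    exclude_clusters: set[str] | None = None,
) -> ClusterProfileMatrix:
    """Per-gene arithmetic mean of expression within each cluster.

    ``exclude_clusters`` drops populations before averaging (e.g. cortex
    and immune clusters in cross-tissue comparisons).
    """
    labels = assignment.labels_for(norm_matrix.cell_ids)
    exclude = exclude_clusters or set()
    cols = {}
    for cl in assignment.clusters():
        if cl in exclude:
            continue
        member = labels == cl
        if not member.any():
            continue
        cols[cl] = norm_matrix.values[:, member].mean(axis=1)
    if not cols:
        raise ValidationError("no clusters left to average")
    frame = pd.DataFrame(cols, index=norm_matrix.gene_ids)
    prov = {cl: norm_matrix.dataset_id for cl in frame.columns}
    return ClusterProfileMatrix(frame=frame, provenance=prov)


def quantile_normalize(profiles: ClusterProfileMatrix) -> ClusterProfileMatrix:
    """Classic quantile normalization across the profile columns.

    Each column's sorted values are replaced by the across-column mean of
    the sorted values at each rank; tied values within a column receive
    the mean of their tied ranks' targets.
    """
    x = profiles.frame.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least 2 columns")
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        col_sorted = x[order, j]
        assigned = np.empty_like(target)
        start = 0
        for stop in range(1, len(col_sorted) + 1):
            if stop == len(col_sorted) or col_sorted[stop] != col_sorted[start]:
                assigned[start:stop] = target[start:stop].mean()
                start = stop
        out[order, j] = assigned
    frame = pd.DataFrame(out, index=profiles.frame.index, columns=profiles.frame.columns)
    return ClusterProfileMatrix(frame=frame, provenance=dict(profiles.provenance))


def euclidean_distance_matrix(profiles: ClusterProfileMatrix) -> pd.DataFrame:
    """Pairwise Euclidean distances between cluster profiles."""
    if len(profiles.clusters) < 2:
        raise ValidationError("need at least 2 clusters")
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(profiles.frame.to_numpy().T, metric="euclidean")
    )
    return pd.DataFrame(d, index=profiles.clusters, columns=profiles.clusters)


def ward2_linkage(distance_matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Agglomeration under the Ward-2 criterion (Lance-Williams update on
    squared distances, merge heights on the original distance scale).

    At each step the pair with the smallest updated squared distance is
    merged; ties break on the lowest pair of active-cluster indices, so
    the tree is deterministic.  Returns a scipy-style linkage matrix.
    """
    d = np.asarray(
        distance_matrix.to_numpy() if isinstance(distance_matrix, pd.DataFrame)
        else distance_matrix,
        dtype=float,
    )
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValidationError("expected a symmetric distance matrix with zero diagonal")
    d2 = d**2
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    # squared-distance store keyed by frozen pairs of current cluster ids
    pair_d2: dict[tuple[int, int], float] = {
        (i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)
    }
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = min(
            ((pair_d2[(min(a, b), max(a, b))], (min(a, b), max(a, b)))
             for idx, a in enumerate(active) for b in active[idx + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        d2_ij, (i, j) = best
        ni, nj = size[i], size[j]
        linkage[step] = [i, j, np.sqrt(d2_ij), ni + nj]
        for k in active:
            if k in (i, j):
                continue
            nk = size[k]
            dik = pair_d2[(min(i, k), max(i, k))]
            djk = pair_d2[(min(j, k), max(j, k))]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * d2_ij) / (ni + nj + nk)
            pair_d2[(min(k, next_id), max(k, next_id))] = new
        active = [a for a in active if a not in (i, j)] + [next_id]
        size[next_id] = ni + nj
        next_id += 1
    return linkage


def clades_from_linkage(linkage: np.ndarray, labels: list[str]) -> list[frozenset[str]]:
    """Leaf-label set of each internal node, in merge order."""
    n = len(labels)
    members: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = []
    for row in range(linkage.shape[0]):
        merged = members[int(linkage[row, 0])] | members[int(linkage[row, 1])]
        members[n + row] = merged
        clades.append(merged)
    return clades


def _au_from_multiscale(
    bp_by_scale: np.ndarray, scales: np.ndarray, n_boot: int
) -> float:
    """Approximately unbiased p (fraction) from per-scale BP values.

    Weighted least squares of z_r = Phi^{-1}(1 - BP_r) on
    (sqrt(r), 1/sqrt(r)); the AU value is 1 - Phi(v - c) for fitted
    coefficients (v, c).  Degenerate branches (BP 0 or 1 at every scale)
    keep their unit-scale BP.
    """
    if np.all(bp_by_scale == 0.0) or np.all(bp_by_scale == 1.0):
        return float(bp_by_scale[np.argmin(np.abs(scales - 1.0))])
    eps = 1.0 / (2.0 * n_boot)
    bp = np.clip(bp_by_scale, eps, 1.0 - eps)
    z = scipy.stats.norm.ppf(1.0 - bp)
    w = n_boot * scipy.stats.norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    design = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    wd = design * w[:, None]
    try:
        coef = np.linalg.solve(design.T @ wd, wd.T @ z)
    except np.linalg.LinAlgError:
        return float(bp[np.argmin(np.abs(scales - 1.0))])
    v, c = coef
    return float(1.0 - scipy.stats.norm.cdf(v - c))


def bootstrap_branch_support(
    profiles: ClusterProfileMatrix,
    n_boot: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
) -> SupportedDendrogram:
    """Multiscale gene bootstrap of the Ward-2 dendrogram.

    Genes (rows) are resampled with replacement at each scale r with
    sample size round(r * n_genes); BP of a branch is the fraction of
    unit-scale replicates whose tree contains the branch's leaf set; AU
    comes from the weighted multiscale fit.  All randomness flows through
    one generator seeded with ``seed``.
    """
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} gives coarse support estimates; 1000 is typical",
            stacklevel=2,
        )
    scales = np.asarray(sorted(scales), dtype=float)
    if not np.any(np.isclose(scales, 1.0)):
        raise ValidationError("scales must include 1.0 (the unit scale)")
    x = profiles.frame.to_numpy(dtype=float)
    labels = profiles.clusters
    n_genes = x.shape[0]
    dist = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(x.T, metric="euclidean")
    )
    linkage = ward2_linkage(dist)
    observed = clades_from_linkage(linkage, labels)
    rng = np.random.default_rng(seed)

    counts = np.zeros((scales.size, len(observed)), dtype=np.int64)
    clade_index = {clade: i for i, clade in enumerate(observed)}
    for si, r in enumerate(scales):
        m = max(2, int(round(r * n_genes)))
        for _ in range(n_boot):
            idx = rng.integers(0, n_genes, size=m)
            sub = x[idx, :]
            d = scipy.spatial.distance.squareform(
                scipy.spatial.distance.pdist(sub.T, metric="euclidean")
            )
            for clade in clades_from_linkage(ward2_linkage(d), labels):
                pos = clade_index.get(clade)
                if pos is not None:
                    counts[si, pos] += 1
    bp_frac = counts / float(n_boot)
    unit = int(np.argmin(np.abs(scales - 1.0)))
    bp = 100.0 * bp_frac[unit]
    au = np.array(
        [100.0 * _au_from_multiscale(bp_frac[:, b], scales, n_boot)
         for b in range(len(observed))]
    )
    return SupportedDendrogram(
        labels=list(labels), linkage=linkage, bp=bp, au=np.clip(au, 0.0, 100.0)
    )
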