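"""Synthetic paired datasets with the structure the analysis assumes.

The generator emulates a tumor/normal-tissue pair of single-cell count
matrices with planted transcriptional structure, so that every downstream
stage can be exercised and scored against a known truth:

* negative-binomial counts with gene-level dispersion over log-normal
  baseline means;
* per-cluster unique marker genes with a configured log2 fold-change;
* one signature shared between a designated cluster of each dataset,
  linked through 1:1 ortholog entries (a fraction of non-planted genes
  get 1:many entries to exercise the restriction step);
* a sample/group layout with one cluster over-represented in the "high"
  group;
* a CNV clone: a configured fraction of one cluster's cells carries a
  rearranged segment over a region of interest, everyone else only
  neutral-dominated segments;
* a bulk cohort whose survival hazard and age at diagnosis covary with
  the planted signature's average expression, with risk groups assigned
  by signature tertiles.

All randomness flows through one ``numpy.random.default_rng(seed)``; the
same config and seed reproduce the outputs exactly, and every planted
quantity is recorded in the truth manifest.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ClusterAssignment,
    CNVSegmentTable,
    ExpressionMatrix,
    NormalizedMatrix,
    OrthologMap,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "generate_paired_datasets",
    "generate_cnv_table",
    "generate_bulk_cohort",
]


class ConfigError(ValidationError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Counts follow NB(mean mu, dispersion alpha) with var = mu + alpha mu^2;
    baseline means are log-normal across genes.  Fold-changes are log2.
    """

    n_clusters: int = 4
    cells_per_cluster: int = 100
    n_genes: int = 2000
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    markers_per_cluster: int = 20
    marker_log2fc: float = 2.0
    shared_signature_size: int = 30
    shared_log2fc: float = 2.0
    ortholog_one_to_many_fraction: float = 0.05
    # sample/group layout for composition tests
    n_samples: int = 6
    composition_fold: float = 3.0
    # CNV clone
    cnv_region: tuple[str, int, int] = ("chr17", 25_000_000, 83_000_000)
    cnv_state: int = 4
    cnv_penetrance: float = 0.6
    # bulk cohort
    bulk_n_samples: int = 200
    hazard_ratio: float = 3.0
    age_correlation: float = 0.5
    bulk_noise_sd: float = 1.0
    baseline_median_efs_days: float = 1200.0
    censor_horizon_days: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_clusters",
            "cells_per_cluster",
            "n_genes",
            "markers_per_cluster",
            "shared_signature_size",
            "n_samples",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 <= self.cnv_penetrance <= 1.0):
            raise ConfigError("cnv_penetrance must be in [0, 1]")
        if not np.isfinite(self.marker_log2fc) or not np.isfinite(self.shared_log2fc):
            raise ConfigError("fold-changes must be finite")
        if not (1 <= self.cnv_state <= 6) or self.cnv_state == 3:
            raise ConfigError("cnv_state must be a non-neutral state in 1..6")
        chrom, start, end = self.cnv_region
        if not chrom or start >= end:
            raise ConfigError("cnv_region must be (chrom, start < end)")
        needed = (
            self.shared_signature_size + 2 * self.n_clusters * self.markers_per_cluster
        )
        if needed > self.n_genes:
            raise ConfigError(
                f"planted genes ({needed}) exceed n_genes ({self.n_genes})"
            )
        if self.bulk_n_samples < 10:
            raise ConfigError("bulk cohort needs at least 10 samples")


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draw with var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    if dispersion <= 0:
        return rng.poisson(means)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means * dispersion)
    return rng.poisson(lam)


def _cluster_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


def _simulate_dataset(
    rng: np.random.Generator,
    config: SimulationConfig,
    gene_ids: list[str],
    cell_prefix: str,
    cluster_prefix: str,
    marker_blocks: dict[str, list[int]],
    shared_cluster: str,
    shared_idx: list[int],
    shared_log2fc: float,
    composition_cluster: str,
) -> tuple[ExpressionMatrix, ClusterAssignment]:
    clusters = _cluster_names(cluster_prefix, config.n_clusters)
    base = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes
    )
    cells: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for cl in clusters:
        mu = base.copy()
        for idx in marker_blocks.get(cl, []):
            mu[idx] *= 2.0**config.marker_log2fc
        if cl == shared_cluster:
            mu[shared_idx] = base[shared_idx] * 2.0**shared_log2fc
        mu_mat = np.repeat(mu[:, None], config.cells_per_cluster, axis=1)
        blocks.append(_nb_counts(rng, mu_mat, config.dispersion))
        cells.extend(
            f"{cell_prefix}_{cl}_c{j + 1}" for j in range(config.cells_per_cluster)
        )
        labels.extend([cl] * config.cells_per_cluster)
    counts = np.concatenate(blocks, axis=1)

    samples = [f"{cell_prefix}_S{i + 1}" for i in range(config.n_samples)]
    half = config.n_samples // 2
    group_of_sample = {
        s: ("high" if i < half else "low") for i, s in enumerate(samples)
    }
    weights = np.ones(config.n_samples)
    sample_ids: list[str] = []
    for cl in labels:
        w = weights.copy()
        if cl == composition_cluster:
            w[:half] *= config.composition_fold
        w = w / w.sum()
        sample_ids.append(samples[rng.choice(config.n_samples, p=w)])

    matrix = ExpressionMatrix(
        gene_ids=gene_ids, cell_ids=cells, counts=counts, dataset_id=cell_prefix
    )
    assignment = ClusterAssignment(
        cell_ids=cells,
        cluster_labels=labels,
        sample_ids=sample_ids,
        group_of_sample=group_of_sample,
    )
    return matrix, assignment


def generate_paired_datasets(
    config: SimulationConfig,
) -> tuple[
    ExpressionMatrix,
    ExpressionMatrix,
    ClusterAssignment,
    ClusterAssignment,
    OrthologMap,
    dict[str, Any],
]:
    """Two related datasets with planted unique and shared signatures.

    Dataset 1 carries gene ids ``gA...``, dataset 2 ``gB...``; every gene
    has a 1:1 ortholog entry ``gA_i <-> gB_i`` except a configured
    fraction of non-planted genes, which receive an extra 1:many pair.
    The shared signature is elevated (at ``shared_log2fc``) in the first
    cluster of dataset 1 and the second cluster of dataset 2.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_genes))
    genes_a = [f"gA{i + 1:0{width}d}" for i in range(config.n_genes)]
    genes_b = [f"gB{i + 1:0{width}d}" for i in range(config.n_genes)]

    shared_idx = list(range(config.shared_signature_size))
    cursor = config.shared_signature_size
    clusters_a = _cluster_names("A", config.n_clusters)
    clusters_b = _cluster_names("B", config.n_clusters)
    markers_a: dict[str, list[int]] = {}
    for cl in clusters_a:
        markers_a[cl] = list(range(cursor, cursor + config.markers_per_cluster))
        cursor += config.markers_per_cluster
    markers_b: dict[str, list[int]] = {}
    for cl in clusters_b:
        markers_b[cl] = list(range(cursor, cursor + config.markers_per_cluster))
        cursor += config.markers_per_cluster

    shared_cluster_a = clusters_a[0]
    shared_cluster_b = clusters_b[1 % config.n_clusters]
    composition_a = clusters_a[-1]
    composition_b = clusters_b[-1]

    em1, asg1 = _simulate_dataset(
        rng, config, genes_a, "ds1", "A", markers_a,
        shared_cluster_a, shared_idx, config.shared_log2fc, composition_a,
    )
    em2, asg2 = _simulate_dataset(
        rng, config, genes_b, "ds2", "B", markers_b,
        shared_cluster_b, shared_idx, config.shared_log2fc, composition_b,
    )

    pairs = list(zip(genes_a, genes_b))
    planted = set(shared_idx)
    for idxs in (*markers_a.values(), *markers_b.values()):
        planted.update(idxs)
    eligible = np.array([i for i in range(config.n_genes) if i not in planted])
    n_multi = int(round(config.ortholog_one_to_many_fraction * config.n_genes))
    n_multi = min(n_multi, eligible.size)
    multi_idx = rng.choice(eligible, size=n_multi, replace=False)
    for i in sorted(multi_idx):
        pairs.append((genes_a[i], f"{genes_b[i]}_alt"))
    omap = OrthologMap(pairs)

    truth: dict[str, Any] = {
        "seed": config.seed,
        "config": asdict(config),
        "unique_markers": {
            "ds1": {cl: [genes_a[i] for i in idxs] for cl, idxs in markers_a.items()},
            "ds2": {cl: [genes_b[i] for i in idxs] for cl, idxs in markers_b.items()},
        },
        "shared_signature": {
            "cluster_ds1": shared_cluster_a,
            "cluster_ds2": shared_cluster_b,
            "genes_ds1": [genes_a[i] for i in shared_idx],
            "genes_ds2": [genes_b[i] for i in shared_idx],
        },
        "one_to_many_genes_a": [genes_a[i] for i in sorted(multi_idx)],
        "composition": {
            "ds1": {"cluster": composition_a, "group": "high",
                    "fold": config.composition_fold},
            "ds2": {"cluster": composition_b, "group": "high",
                    "fold": config.composition_fold},
        },
        "cnv_clone": {
            "cluster": shared_cluster_a,
            "region": list(config.cnv_region),
            "state": config.cnv_state,
            "penetrance": config.cnv_penetrance,
        },
    }
    return em1, em2, asg1, asg2, omap, truth


#: neutral-dominated background segment probabilities (p3 = 0.9)
_NEUTRAL_PROBS = (0.02, 0.02, 0.90, 0.02, 0.02, 0.02)
_BACKGROUND_REGIONS = (
    ("chr1", 0, 120_000_000),
    ("chr2", 0, 120_000_000),
    ("chr7", 0, 100_000_000),
    ("chr11", 0, 100_000_000),
)


def _clone_probs(state: int) -> tuple[float, ...]:
    """High mass on the clone state, neutral mass 0.05 (passes the
    rearrangement-likelihood filter)."""
    probs = [0.025] * 6
    probs[2] = 0.05
    probs[state - 1] = 1.0 - (0.05 + 0.025 * 4)
    return tuple(probs)


def generate_cnv_table(
    config: SimulationConfig,
    assignment: ClusterAssignment,
    clone_cluster: str | None = None,
) -> tuple[CNVSegmentTable, dict[str, Any]]:
    """Per-cell CNV segments with a planted clone in one cluster.

    Clone-cluster cells carry, with probability ``cnv_penetrance``, a
    segment over the configured region with most of its probability mass
    on the configured state; every other segment in the table is
    neutral-dominated.  Returns the table and a truth record of carrier
    cells.
    """
    clone_cluster = clone_cluster or assignment.clusters()[0]
    if clone_cluster not in assignment.clusters():
        raise ConfigError(f"clone cluster {clone_cluster!r} not in assignment")
    rng = np.random.default_rng(config.seed + 1)
    chrom, start, end = config.cnv_region
    rows: list[tuple] = []
    carriers: list[str] = []
    for cell, cl in zip(assignment.cell_ids, assignment.cluster_labels):
        for bg_chrom, bg_start, bg_end in _BACKGROUND_REGIONS:
            rows.append((cell, bg_chrom, bg_start, bg_end, *_NEUTRAL_PROBS))
        is_carrier = cl == clone_cluster and rng.random() < config.cnv_penetrance
        if is_carrier:
            rows.append((cell, chrom, start, end, *_clone_probs(config.cnv_state)))
            carriers.append(cell)
        else:
            # same region, neutral-dominated, so every cell has coverage
            rows.append((cell, chrom, start, end, *_NEUTRAL_PROBS))
    frame = pd.DataFrame(
        rows, columns=["cell_id", "chrom", "start", "end",
                       "p1", "p2", "p3", "p4", "p5", "p6"]
    )
    truth = {
        "clone_cluster": clone_cluster,
        "carrier_cells": carriers,
        "region": [chrom, start, end],
        "state": config.cnv_state,
        "direction": "gain" if config.cnv_state > 3 else "loss",
    }
    return CNVSegmentTable(frame), truth


def generate_bulk_cohort(
    config: SimulationConfig,
    signature_genes: list[str],
    gene_universe: list[str],
) -> tuple[NormalizedMatrix, ClinicalTable, dict[str, Any]]:
    """Bulk cohort whose outcome covaries with a planted signature.

    A latent per-sample activity a ~ N(0, 1) drives: signature-gene
    expression (RPM-like, log2 RPM = 5 + a + noise), an exponential
    event-time draw with hazard proportional to hazard_ratio ** a, and
    age at diagnosis with the configured Pearson coefficient.  Risk
    groups are the tertiles of the per-sample signature average (top
    tertile = high).  Event times are administratively censored at the
    configured horizon.
    """
    missing = [g for g in signature_genes if g not in set(gene_universe)]
    if missing:
        raise ConfigError(f"signature genes outside the universe: {missing[:5]}")
    rng = np.random.default_rng(config.seed + 2)
    n = config.bulk_n_samples
    samples = [f"bulk_{i + 1}" for i in range(n)]
    activity = rng.normal(size=n)

    sig_set = set(signature_genes)
    log2_expr = np.empty((len(gene_universe), n))
    for i, g in enumerate(gene_universe):
        noise = rng.normal(scale=config.bulk_noise_sd, size=n)
        log2_expr[i] = 5.0 + (activity + noise if g in sig_set else noise)
    values = 2.0**log2_expr

    sig_rows = [i for i, g in enumerate(gene_universe) if g in sig_set]
    sig_avg = log2_expr[sig_rows].mean(axis=0)
    tertiles = np.quantile(sig_avg, [1 / 3, 2 / 3])
    risk = np.where(
        sig_avg <= tertiles[0], "low",
        np.where(sig_avg <= tertiles[1], "intermediate", "high"),
    )

    lam0 = np.log(2.0) / config.baseline_median_efs_days
    lam = lam0 * config.hazard_ratio**activity
    raw_times = rng.exponential(1.0 / lam)
    efs_days = np.minimum(raw_times, config.censor_horizon_days)
    efs_event = raw_times <= config.censor_horizon_days

    rho = config.age_correlation
    age_noise = rng.normal(size=n)
    age_latent = rho * activity + np.sqrt(max(0.0, 1.0 - rho**2)) * age_noise
    age_months = np.clip(36.0 + 18.0 * age_latent, 0.0, None)

    bulk = NormalizedMatrix(
        gene_ids=list(gene_universe),
        cell_ids=samples,
        values=values,
        transform_tag="standardized",
        dataset_id="bulk",
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "risk_group": risk,
                "age_months": age_months,
                "efs_days": efs_days,
                "efs_event": efs_event.astype(int),
            }
        )
    )
    truth = {
        "signature_genes": list(signature_genes),
        "hazard_ratio": config.hazard_ratio,
        "age_correlation": config.age_correlation,
        "activity": activity.tolist(),
        "worse_direction": "high-score" if config.hazard_ratio > 1 else "none",
    }
    return bulk, clinical, truth
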