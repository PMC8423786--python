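"""Shared domain types for the signature-sharing pipeline.

Every container validates its invariants on construction so that file
readers, the simulator and the analysis stages all fail early on malformed
input.  Genomic coordinates are 0-based half-open throughout (BED
convention on disk and in memory).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "ExpressionMatrix",
    "NormalizedMatrix",
    "ClusterAssignment",
    "GeneSet",
    "OrthologMap",
    "CNVSegmentTable",
    "ClinicalTable",
    "TestResult",
    "RISK_GROUPS",
    "NEUTRAL_STATE",
]

RISK_GROUPS = ("high", "intermediate", "low")

#: copy-number states are 1..6; 3 is the diploid/neutral state
NEUTRAL_STATE = 3


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


class FormatError(ValueError):
    """A file on disk cannot be parsed into the expected structure."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Raw gene-by-cell read counts.

    ``counts`` has shape (n_genes, n_cells); entries are finite,
    non-negative integers (stored as an integer array).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(counts)):
            raise ValidationError("counts contain non-finite values")
        if np.any(counts < 0):
            raise ValidationError("counts contain negative values")
        self.counts = counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in keep],
            counts=self.counts[:, keep],
            dataset_id=self.dataset_id,
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in keep],
            cell_ids=list(self.cell_ids),
            counts=self.counts[keep, :],
            dataset_id=self.dataset_id,
        )


TRANSFORM_TAGS = ("cp10k", "log1p_cp10k", "standardized")


@dataclass
class NormalizedMatrix:
    """Gene-by-cell expression after library-size scaling.

    ``transform_tag`` records the units: counts per 10,000 (``cp10k``),
    natural log of cp10k + 1 (``log1p_cp10k``), or externally supplied
    standardized magnitudes (``standardized``).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    transform_tag: str = "cp10k"
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.transform_tag not in TRANSFORM_TAGS:
            raise ValidationError(f"unknown transform_tag {self.transform_tag!r}")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match identifier lists"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("normalized values contain non-finite entries")
        self.values = values

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels, sample of origin, and per-sample group label.

    ``group_of_sample`` maps each sample to a categorical label such as a
    risk group or a tumor stage; it may be empty when composition tests are
    not requested.
    """

    cell_ids: list[str]
    cluster_labels: list[str]
    sample_ids: list[str]
    group_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.cell_ids, "cell")
        n = len(self.cell_ids)
        if len(self.cluster_labels) != n or len(self.sample_ids) != n:
            raise ValidationError("cluster/sample lists must match cell list length")
        if any(not str(lbl) for lbl in self.cluster_labels):
            raise ValidationError("cluster labels must be non-empty")
        self.cluster_labels = [str(x) for x in self.cluster_labels]
        self.sample_ids = [str(x) for x in self.sample_ids]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cluster_of(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.cluster_labels))

    def clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cluster_labels:
            seen.setdefault(c, None)
        return list(seen)

    def labels_for(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Cluster labels aligned to an arbitrary cell order."""
        lut = self.cluster_of()
        missing = [c for c in cell_ids if c not in lut]
        if missing:
            raise ValidationError(f"cells without cluster label: {missing[:5]}")
        return np.array([lut[c] for c in cell_ids])

    def group_labels(self) -> np.ndarray:
        """Per-cell group label via the cell's sample."""
        missing = sorted({s for s in self.sample_ids if s not in self.group_of_sample})
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")
        return np.array([self.group_of_sample[s] for s in self.sample_ids])

    def subset(self, keep_cells: Iterable[str]) -> "ClusterAssignment":
        keep = set(keep_cells)
        idx = [i for i, c in enumerate(self.cell_ids) if c in keep]
        return ClusterAssignment(
            cell_ids=[self.cell_ids[i] for i in idx],
            cluster_labels=[self.cluster_labels[i] for i in idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            group_of_sample=dict(self.group_of_sample),
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (symbols or stable IDs, opaque strings)."""

    name: str
    genes: frozenset[str]
    source_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


class OrthologMap:
    """Cross-dataset gene correspondences with per-gene mapping degrees.

    The map is a list of (gene_a, gene_b) pairs; ``degree_a``/``degree_b``
    count pairs per gene.  The 1:1 subset contains exactly the pairs whose
    genes have degree 1 on both sides.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        frame = pd.DataFrame(list(pairs), columns=["gene_a", "gene_b"], dtype=str)
        frame = frame.drop_duplicates(ignore_index=True)
        self.pairs = frame
        self.degree_a: dict[str, int] = frame["gene_a"].value_counts().to_dict()
        self.degree_b: dict[str, int] = frame["gene_b"].value_counts().to_dict()
        one = frame[
            frame["gene_a"].map(self.degree_a).eq(1)
            & frame["gene_b"].map(self.degree_b).eq(1)
        ]
        self._a2b: dict[str, str] = dict(zip(one["gene_a"], one["gene_b"]))
        self._b2a: dict[str, str] = dict(zip(one["gene_b"], one["gene_a"]))

    def __len__(self) -> int:
        return len(self.pairs)

    def one_to_one(self, direction: str = "a2b") -> Mapping[str, str]:
        """Bijective translation table over the 1:1 subset."""
        if direction == "a2b":
            return dict(self._a2b)
        if direction == "b2a":
            return dict(self._b2a)
        raise ValueError(f"direction must be 'a2b' or 'b2a', got {direction!r}")


CNV_PROB_COLS = ["p1", "p2", "p3", "p4", "p5", "p6"]
_PROB_TOL = 1e-6


class CNVSegmentTable:
    """Per-cell genomic segments with six-state copy-number probabilities.

    States: 1 complete loss, 2 single-copy loss, 3 neutral, 4 single-copy
    gain, 5 two-copy gain, 6 gain of more than two copies.  The
    rearrangement likelihood of a segment is the summed probability of the
    five non-neutral states.  Coordinates are 0-based half-open.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["cell_id", "chrom", "start", "end", *CNV_PROB_COLS]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise FormatError(f"CNV table missing columns: {missing}")
        frame = frame.copy().reset_index(drop=True)
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
        if (frame["start"] >= frame["end"]).any():
            raise ValidationError("CNV segments require start < end (half-open)")
        probs = frame[CNV_PROB_COLS].to_numpy(dtype=float)
        if np.any(probs < -_PROB_TOL) or np.any(probs > 1 + _PROB_TOL):
            raise ValidationError("state probabilities outside [0, 1]")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _PROB_TOL):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"state probabilities of row {bad} sum to {sums[bad]:.6g}, not 1"
            )
        frame["most_likely_state"] = probs.argmax(axis=1) + 1
        frame["rearrangement_likelihood"] = 1.0 - probs[:, NEUTRAL_STATE - 1]
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def cells(self) -> list[str]:
        return self.frame["cell_id"].unique().tolist()


class ClinicalTable:
    """Per-sample clinical covariates for the bulk cohort.

    ``age_months`` is age at diagnosis in months; ``efs_days``/``efs_event``
    are event-free survival time (days) and event indicator.
    """

    COLUMNS = ["sample_id", "risk_group", "age_months", "efs_days", "efs_event"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        frame = frame.copy().reset_index(drop=True)
        frame["sample_id"] = frame["sample_id"].astype(str)
        _check_unique(frame["sample_id"].tolist(), "sample")
        bad_risk = set(frame["risk_group"].astype(str)) - set(RISK_GROUPS)
        if bad_risk:
            raise ValidationError(f"unknown risk_group labels: {sorted(bad_risk)}")
        for col in ("age_months", "efs_days"):
            frame[col] = frame[col].astype(float)
            if (frame[col] < 0).any():
                raise ValidationError(f"{col} must be >= 0")
        frame["efs_event"] = frame["efs_event"].astype(int).astype(bool)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TestResult:
    """Outcome of one hypothesis test, with a multiplicity-adjusted q-value.

    ``direction`` is "up"/"down" for signed contrasts, "none" otherwise.
    """

    unit_id: str
    statistic: float
    p_value: float
    q_value: float = float("nan")
    direction: str = "none"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if np.isfinite(self.q_value) and self.q_value < self.p_value - 1e-12:
            raise ValidationError("q_value must be >= p_value")
        if self.direction not in ("up", "down", "none"):
            raise ValidationError(f"bad direction {self.direction!r}")
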