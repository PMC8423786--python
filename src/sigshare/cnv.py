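"""Downstream analysis of externally produced per-cell copy-number calls.

Segments arrive with six-state probability vectors (1 = complete loss,
2 = one-copy loss, 3 = neutral, 4 = one-copy gain, 5 = two-copy gain,
6 = gain of more than two copies).  A segment's rearrangement likelihood
is the summed probability of the five non-neutral states; segments with
likelihood > 0.9 (neutral mass <= 0.1) are kept.  Per cell and region of
interest (e.g. 1p loss, 11q loss, 17q gain), the mean most-likely state
over overlapping kept segments classifies the cell as gain (> 3),
loss (< 3) or neutral.  Per sample, cluster enrichment of rearranged
cells is tested with BH-corrected one-sided Fisher exact tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ClusterAssignment,
    CNVSegmentTable,
    NEUTRAL_STATE,
    TestResult,
    ValidationError,
)
from .stats import bh_adjust, fisher_one_sided

__all__ = [
    "RegionQuery",
    "CellRegionState",
    "filter_cnv_calls",
    "region_state_per_cell",
    "cluster_rearrangement_enrichment",
]


@dataclass(frozen=True)
class RegionQuery:
    """A genomic region of interest with its expected direction.

    Coordinates are 0-based half-open.
    """

    name: str
    chrom: str
    start: int
    end: int
    expected_direction: str  # "gain" or "loss"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"region {self.name}: start must be < end")
        if self.expected_direction not in ("gain", "loss"):
            raise ValidationError(
                f"region {self.name}: direction must be 'gain' or 'loss'"
            )


@dataclass
class CellRegionState:
    cell_id: str
    region: str
    mean_state: float  # NaN when no_data
    call: str  # gain | loss | neutral | no_data


def filter_cnv_calls(
    table: CNVSegmentTable, max_neutral_prob: float = 0.1
) -> CNVSegmentTable:
    """Keep segments whose neutral-state probability is <= the threshold,
    i.e. whose rearrangement likelihood exceeds 1 - ``max_neutral_prob``
    (default: true-rearrangement probability > 0.9)."""
    keep = table.frame["p3"] <= max_neutral_prob
    return CNVSegmentTable(table.frame.loc[keep].reset_index(drop=True))


def region_state_per_cell(
    kept_table: CNVSegmentTable,
    region: RegionQuery,
    cells: list[str] | None = None,
    direction_restricted: bool = False,
) -> list[CellRegionState]:
    """Mean most-likely state per cell over segments overlapping the region.

    Overlap is half-open: a segment [s, e) overlaps [start, end) iff
    s < end and e > start.  The call is gain when the mean state exceeds
    the neutral state (3), loss when below, neutral at exactly 3, and
    no_data for cells without an overlapping kept segment.  ``cells``
    fixes the cell universe (typically every profiled cell, from the
    unfiltered table or the cluster assignment); by default only cells
    still present in the filtered table are reported, so pass the full
    list whenever likelihood filtering may have emptied some cells.
    With ``direction_restricted``, only segments already on the region's
    expected side of neutral enter the average.
    """
    frame = kept_table.frame
    hit = (
        (frame["chrom"] == region.chrom)
        & (frame["start"] < region.end)
        & (frame["end"] > region.start)
    )
    sub = frame.loc[hit]
    if direction_restricted:
        side = (
            sub["most_likely_state"] > NEUTRAL_STATE
            if region.expected_direction == "gain"
            else sub["most_likely_state"] < NEUTRAL_STATE
        )
        sub = sub.loc[side]
    means = sub.groupby("cell_id")["most_likely_state"].mean()
    universe = cells if cells is not None else kept_table.frame["cell_id"].unique()
    out: list[CellRegionState] = []
    for cell in universe:
        if cell in means.index:
            m = float(means[cell])
            call = (
                "gain" if m > NEUTRAL_STATE else "loss" if m < NEUTRAL_STATE else "neutral"
            )
        else:
            m, call = float("nan"), "no_data"
        out.append(CellRegionState(cell_id=cell, region=region.name, mean_state=m, call=call))
    return out


def cluster_rearrangement_enrichment(
    states: list[CellRegionState],
    assignment: ClusterAssignment,
    regions: list[RegionQuery] | RegionQuery,
    fdr: float = 0.05,
    exclude_no_data: bool = False,
) -> list[TestResult]:
    """Per-sample, per-cluster enrichment of region rearrangements.

    Each sample is analysed independently.  For every (region, cluster)
    within a sample, a one-sided Fisher test asks whether cells whose
    call matches the region's expected direction are over-represented in
    the cluster; BH spans all (region, cluster) tests within the sample.
    Cells with call neutral count as non-rearranged; ``exclude_no_data``
    drops no_data cells from the table instead of counting them as
    non-rearranged.
    """
    if isinstance(regions, RegionQuery):
        regions = [regions]
    region_by_name = {r.name: r for r in regions}
    state_frame = pd.DataFrame(
        [(s.cell_id, s.region, s.call) for s in states],
        columns=["cell_id", "region", "call"],
    )
    cluster_of = assignment.cluster_of()
    sample_of = dict(zip(assignment.cell_ids, assignment.sample_ids))
    known = state_frame["cell_id"].isin(cluster_of)
    if not known.all():
        warnings.warn(
            f"{(~known).sum()} CNV cells missing from the cluster assignment "
            "were dropped",
            stacklevel=2,
        )
        state_frame = state_frame.loc[known]
    state_frame["cluster"] = state_frame["cell_id"].map(cluster_of)
    state_frame["sample"] = state_frame["cell_id"].map(sample_of)

    results: list[TestResult] = []
    for sample, per_sample in state_frame.groupby("sample"):
        units: list[tuple[str, float, float, str]] = []
        for region_name, per_region in per_sample.groupby("region"):
            region = region_by_name[region_name]
            cells = per_region
            if exclude_no_data:
                cells = cells.loc[cells["call"] != "no_data"]
            rearranged = (cells["call"] == region.expected_direction).to_numpy()
            clusters_here = cells["cluster"].to_numpy()
            for cl in assignment.clusters():
                in_cl = clusters_here == cl
                if not in_cl.any():
                    warnings.warn(
                        f"cluster {cl!r} absent from sample {sample!r}; skipped",
                        stacklevel=2,
                    )
                    continue
                a = int((rearranged & in_cl).sum())
                b = int((~rearranged & in_cl).sum())
                c = int((rearranged & ~in_cl).sum())
                d = int((~rearranged & ~in_cl).sum())
                p = fisher_one_sided([[a, b], [c, d]]).p_value
                units.append((f"{sample}|{region_name}|{cl}", float(a), p, "up"))
        qs = bh_adjust([u[2] for u in units]) if units else np.empty(0)
        for (uid, stat, p, _), q in zip(units, qs):
            results.append(
                TestResult(
                    unit_id=uid,
                    statistic=stat,
                    p_value=p,
                    q_value=float(q),
                    direction="up" if q < fdr else "none",
                )
            )
    return results
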