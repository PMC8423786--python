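"""Readers and writers for every external format the pipeline touches.

Formats
-------
* Expression: Matrix Market ``.mtx`` (coordinate, integer) plus one-column
  ``genes.tsv`` / ``cells.tsv`` sidecars, or a dense TSV with gene rows and
  cell columns.
* Gene sets: GMT (name, description, tab-separated genes).
* Ortholog map: headered TSV with columns ``gene_a``, ``gene_b``.
* CNV segments: BED-like headered TSV with columns ``cell_id``, ``chrom``,
  ``start``, ``end``, ``p1``..``p6`` (0-based half-open coordinates).
* Clinical table: headered TSV with ``sample_id``, ``risk_group``,
  ``age_months``, ``efs_days``, ``efs_event``.
* Cluster assignment: headered TSV with ``cell_id``, ``cluster``,
  ``sample_id`` and an optional per-sample ``group`` column.

All write/read pairs round-trip exactly (identifier order canonicalized
where noted on the writer).
"""
from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    CNV_PROB_COLS,
    ClinicalTable,
    ClusterAssignment,
    CNVSegmentTable,
    ExpressionMatrix,
    FormatError,
    GeneSet,
    OrthologMap,
    ValidationError,
)

__all__ = [
    "read_expression_bundle",
    "write_expression_bundle",
    "read_dense_expression",
    "write_dense_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_cnv_table",
    "write_cnv_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_cluster_assignment",
    "write_cluster_assignment",
]


def _read_id_column(path: str, what: str) -> list[str]:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if not ids:
        raise FormatError(f"empty {what} list at {path}")
    return ids


def read_expression_bundle(
    matrix_path: str, genes_path: str, cells_path: str, dataset_id: str = ""
) -> ExpressionMatrix:
    """Read a Matrix Market coordinate file with gene/cell sidecar lists.

    MTX entries are 1-based on disk; in-memory indices are 0-based, so disk
    entry ``i j v`` lands at ``counts[i-1, j-1]``.
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}")
    dense = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.int64
    )
    genes = _read_id_column(genes_path, "gene")
    cells = _read_id_column(cells_path, "cell")
    if dense.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix {dense.shape} does not match {len(genes)} genes "
            f"x {len(cells)} cells"
        )
    return ExpressionMatrix(genes, cells, dense, dataset_id=dataset_id)


def write_expression_bundle(
    matrix: ExpressionMatrix, matrix_path: str, genes_path: str, cells_path: str
) -> None:
    scipy.io.mmwrite(
        matrix_path, scipy.sparse.coo_matrix(matrix.counts), field="integer"
    )
    # mmwrite appends .mtx when the suffix is absent; mirror that quirk
    if not os.path.exists(matrix_path) and os.path.exists(matrix_path + ".mtx"):
        os.replace(matrix_path + ".mtx", matrix_path)
    with open(genes_path, "w") as fh:
        fh.write("".join(g + "\n" for g in matrix.gene_ids))
    with open(cells_path, "w") as fh:
        fh.write("".join(c + "\n" for c in matrix.cell_ids))


def read_dense_expression(path: str, dataset_id: str = "") -> ExpressionMatrix:
    """Dense TSV: first column gene ids, header row cell ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    genes = frame.index.astype(str).tolist()
    cells = frame.columns.astype(str).tolist()
    return ExpressionMatrix(genes, cells, frame.to_numpy(), dataset_id=dataset_id)


def write_dense_expression(matrix: ExpressionMatrix, path: str) -> None:
    frame = pd.DataFrame(matrix.counts, index=matrix.gene_ids, columns=matrix.cell_ids)
    frame.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_sets(path: str) -> list[GeneSet]:
    """Read a GMT file; duplicate genes within a line are collapsed."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(name=name, genes=genes, source_tag=desc))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str) -> None:
    """Write GMT with genes in canonical (sorted) order."""
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source_tag, *gs.sorted_genes()]) + "\n")


def read_ortholog_map(path: str) -> OrthologMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_a", "gene_b"):
        if col not in frame.columns:
            raise FormatError(f"ortholog TSV missing column {col!r}")
    return OrthologMap(frame[["gene_a", "gene_b"]].itertuples(index=False, name=None))


def write_ortholog_map(omap: OrthologMap, path: str) -> None:
    omap.pairs.sort_values(["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_cnv_table(path: str) -> CNVSegmentTable:
    frame = pd.read_csv(path, sep="\t")
    return CNVSegmentTable(frame)


def write_cnv_table(table: CNVSegmentTable, path: str) -> None:
    cols = ["cell_id", "chrom", "start", "end", *CNV_PROB_COLS]
    table.frame[cols].to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str) -> ClinicalTable:
    frame = pd.read_csv(path, sep="\t")
    return ClinicalTable(frame)


def write_clinical_table(table: ClinicalTable, path: str) -> None:
    out = table.frame.copy()
    out["efs_event"] = out["efs_event"].astype(int)
    out[ClinicalTable.COLUMNS].to_csv(path, sep="\t", index=False)


def read_cluster_assignment(path: str) -> ClusterAssignment:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "cluster", "sample_id"):
        if col not in frame.columns:
            raise FormatError(f"cluster TSV missing column {col!r}")
    groups: dict[str, str] = {}
    if "group" in frame.columns:
        per_sample = frame.groupby("sample_id")["group"].nunique()
        conflicted = per_sample[per_sample > 1].index.tolist()
        if conflicted:
            raise ValidationError(
                f"samples with conflicting group labels: {conflicted[:5]}"
            )
        groups = frame.drop_duplicates("sample_id").set_index("sample_id")[
            "group"
        ].to_dict()
    return ClusterAssignment(
        cell_ids=frame["cell_id"].tolist(),
        cluster_labels=frame["cluster"].tolist(),
        sample_ids=frame["sample_id"].tolist(),
        group_of_sample=groups,
    )


def write_cluster_assignment(assignment: ClusterAssignment, path: str) -> None:
    frame = pd.DataFrame(
        {
            "cell_id": assignment.cell_ids,
            "cluster": assignment.cluster_labels,
            "sample_id": assignment.sample_ids,
        }
    )
    if assignment.group_of_sample:
        frame["group"] = [
            assignment.group_of_sample.get(s, "") for s in assignment.sample_ids
        ]
    frame.to_csv(path, sep="\t", index=False)
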