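import numpy as np
import pytest

from sigshare.datatypes import ClusterAssignment, ExpressionMatrix, NormalizedMatrix
from sigshare.simulate import SimulationConfig, generate_paired_datasets


@pytest.fixture(scope="session")
def sim_config():
    """Small but fully structured paired-dataset configuration."""
    return SimulationConfig(n_genes=600, cells_per_cluster=60, seed=11)


@pytest.fixture(scope="session")
def paired(sim_config):
    """One paired synthetic bundle shared across read-only tests."""
    return generate_paired_datasets(sim_config)


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 cells with easy hand-checkable counts."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["c1", "c2", "c3", "c4"],
        counts=np.array([[1, 0, 2, 0], [2, 3, 0, 1], [1, 1, 2, 3]]),
    )


def make_norm(values, tag="cp10k", genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(
        gene_ids=genes, cell_ids=cells, values=values, transform_tag=tag
    )


def make_assignment(labels, samples=None, groups=None, cells=None):
    labels = list(labels)
    cells = cells or [f"c{j}" for j in range(len(labels))]
    samples = list(samples) if samples is not None else ["s0"] * len(labels)
    return ClusterAssignment(
        cell_ids=cells,
        cluster_labels=labels,
        sample_ids=samples,
        group_of_sample=groups or {},
    )
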