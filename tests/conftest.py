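import numpy as np
import pytest
import scipy.sparse as sp

from difforest.cascade import CascadeConfig
from difforest.network_io import WeightedGraph, from_adjacency, to_transition
from difforest.synthetic import SyntheticConfig, generate_benchmark


def random_graph(
    n: int,
    rng: np.random.Generator,
    density: float = 0.3,
    allow_isolated: bool = False,
) -> WeightedGraph:
    """Random symmetric weighted graph with weights in (0, 1]."""
    upper = np.triu(rng.random((n, n)) < density, k=1)
    w = rng.uniform(0.05, 1.0, size=(n, n))
    a = np.where(upper, w, 0.0)
    a = a + a.T
    if not allow_isolated:
        # connect isolated nodes to a random neighbour so no column is zero
        for i in np.flatnonzero(a.sum(axis=0) == 0):
            j = (i + 1) % n
            a[i, j] = a[j, i] = rng.uniform(0.05, 1.0)
    return from_adjacency(a)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small planted-module benchmark reused across classifier tests."""
    cfg = SyntheticConfig(
        n_genes=120,
        n_labels=6,
        n_networks=2,
        informative_labels_per_network=3,
        labels_per_gene_mean=1.5,
        p_in=0.25,
        p_out=0.02,
        seed=11,
    )
    graphs, labels, manifest = generate_benchmark(cfg)
    return cfg, graphs, labels, manifest


@pytest.fixture()
def small_cascade_config():
    return CascadeConfig(
        n_forests=2,
        n_trees=15,
        cv_folds=3,
        early_stopping_rounds=1,
        max_levels=2,
        seed=5,
    )


@pytest.fixture()
def path_graph():
    """Path 0-1-2 with unit weights."""
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return from_adjacency(a)
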