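import numpy as np
import pytest

from sgcluster.graph import CellGraph, cell_graph
from sgcluster.io import PreprocessConfig, preprocess
from sgcluster.simulate import SimConfig, simulate


def graph_from_adjacency(A) -> CellGraph:
    """Build a CellGraph from a 0/1 adjacency, adding self-loops."""
    A = np.array(A, dtype=np.float64)
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 1.0)
    return CellGraph(adjacency=A, similarity=A.copy())


def random_graph(n: int, p: float, seed: int) -> CellGraph:
    """Random symmetric Erdos-Renyi-ish graph with self-loops."""
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(np.float64)
    return graph_from_adjacency(np.triu(A, 1))


def block_graph(sizes) -> CellGraph:
    """Disjoint union of fully connected blocks (plus self-loops)."""
    n = sum(sizes)
    A = np.zeros((n, n))
    start = 0
    for s in sizes:
        A[start:start + s, start:start + s] = 1.0
        start += s
    return graph_from_adjacency(A)


@pytest.fixture(scope="session")
def small_dataset():
    """Well-separated 3-group simulation, preprocessed, with truth labels."""
    em, labels, _ = simulate(SimConfig(n_cells=150, n_genes=300, n_groups=3, seed=1))
    X = preprocess(em, PreprocessConfig(min_cells=3, min_genes=10, n_hvg=200)).values
    return X, labels


@pytest.fixture(scope="session")
def small_graph(small_dataset):
    X, _ = small_dataset
    return cell_graph(X, k=10)
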