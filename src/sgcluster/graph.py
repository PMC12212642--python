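"""Cell-cell graph construction.

Cells are linked when their expression profiles are similar: a Pearson
correlation matrix is denoised by network-enhancement diffusion (random-walk
smoothing over each cell's strongest affinities, which amplifies
within-community similarity relative to sparse noise edges) and then
sparsified to a symmetric k-nearest-neighbour adjacency with self-loops.
Everything here is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellGraph", "pearson_similarity", "network_enhance", "build_graph",
           "cell_graph"]


@dataclass
class CellGraph:
    """Binary symmetric adjacency (self-loops included) plus its provenance.

    Attributes
    ----------
    adjacency : (N, N) ndarray of {0, 1}
        Symmetric adjacency with unit diagonal.
    similarity : (N, N) ndarray
        The (enhanced) similarity matrix the adjacency was thresholded from.
    """

    adjacency: np.ndarray
    similarity: np.ndarray
    degrees: np.ndarray = field(init=False)

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.diag(A) == 1):
            raise ValueError("adjacency must include self-loops")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = A
        self.degrees = A.sum(axis=1)

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def degree_normalized_adjacency(self) -> np.ndarray:
        """Return ``D^{-1/2} A D^{-1/2}`` (degrees are >= 1 by construction)."""
        inv_sqrt = 1.0 / np.sqrt(self.degrees)
        return self.adjacency * inv_sqrt[:, None] * inv_sqrt[None, :]

    def neighbor_mask(self) -> np.ndarray:
        return self.adjacency > 0

    def to_edge_list(self):
        """Yield (i, j, weight) for the upper triangle, weight from similarity."""
        idx = np.argwhere(np.triu(self.adjacency) > 0)
        for i, j in idx:
            yield int(i), int(j), float(self.similarity[i, j])


def pearson_similarity(X: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between cells (rows of ``X``).

    Cells with zero variance have undefined correlations; their off-diagonal
    similarities are set to 0 with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two cells")
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} cell(s) have zero variance; their similarities are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.corrcoef(X)
    S = np.nan_to_num(S, nan=0.0)
    S[flat, :] = 0.0
    S[:, flat] = 0.0
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def network_enhance(W: np.ndarray, k_ne: int | None = None, n_iter: int = 2) -> np.ndarray:
    """Diffusion-based denoising of a symmetric similarity matrix.

    The diagonal is zeroed and negative affinities clipped to 0 (diffusion
    needs non-negative weights); each row keeps its ``k_ne`` largest entries;
    the truncated matrix is symmetrised and row-normalised into a transition
    matrix P, and the affinities are smoothed as ``W <- P W P^T`` for
    ``n_iter`` steps, then symmetrised.  Block-diagonal structure is
    preserved exactly: diffusion cannot move mass across zero-transition
    blocks.
    """
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    n = W.shape[0]
    if k_ne is None:
        k_ne = min(20, max(1, int(np.ceil(n / 10))))
    if not 1 <= k_ne < n:
        raise ValueError(f"k_ne must be in [1, {n - 1}], got {k_ne}")

    T = np.clip(W.copy(), 0.0, None)
    np.fill_diagonal(T, 0.0)
    # keep each row's k_ne largest affinities
    if k_ne < n - 1:
        cut = np.partition(T, n - 1 - k_ne, axis=1)[:, n - 1 - k_ne]
        T[T < cut[:, None]] = 0.0
    T = (T + T.T) / 2.0
    rows = T.sum(axis=1, keepdims=True)
    P = np.divide(T, rows, out=np.zeros_like(T), where=rows > 0)
    out = T
    for _ in range(int(n_iter)):
        out = P @ out @ P.T
        out = (out + out.T) / 2.0
    return out


def build_graph(W_enh: np.ndarray, k: int = 15) -> CellGraph:
    """Sparsify a similarity matrix into a symmetric KNN adjacency.

    ``A[i, j] = 1`` iff j is among i's k most similar cells or vice versa
    (union symmetrisation); ties at the k-th position are all admitted, so
    the result is deterministic.  Self-loops are added last.
    """
    W = np.asarray(W_enh, dtype=np.float64)
    n = W.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    S = W.copy()
    np.fill_diagonal(S, -np.inf)  # self excluded from neighbour selection
    kth = np.sort(S, axis=1)[:, n - 1 - k]
    A = (S >= kth[:, None]).astype(np.float64)
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 1.0)
    return CellGraph(adjacency=A, similarity=W)


def cell_graph(X: np.ndarray, k: int = 15, k_ne: int | None = None,
               n_iter: int = 2, enhance: bool = True) -> CellGraph:
    """Full pipeline: Pearson similarity -> network enhancement -> KNN graph."""
    S = pearson_similarity(X)
    W = network_enhance(S, k_ne=k_ne, n_iter=n_iter) if enhance else np.clip(S, 0.0, None)
    return build_graph(W, k=k)
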