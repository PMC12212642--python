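"""K-way normalized cut: discrete score, spectral relaxation, trainable loss.

The discrete objective averages, over K clusters, the within-cluster link
mass divided by the total cluster degree:

    score = (1/K) sum_k links(C_k, C_k) / degree(C_k)                  in [0, 1]

Relaxing the one-hot cluster indicator through E_k = D^{1/2} F_k
(F_k^T D F_k)^{-1/2} turns the objective into a trace maximisation over
orthonormal matrices, whose optimum (Ky Fan) is the mean of the K largest
eigenvalues of D^{-1/2} A D^{-1/2}.  The differentiable surrogate used
during training replaces the hard orthonormality constraint with a penalty:

    sg_loss(S) = || (1/N) S^T S - I ||_F^2 - (1/(N K)) tr(S^T D^{-1/2} A D^{-1/2} S)

which any real N x d matrix S (e.g. a network layer's pre-activation) can
be plugged into.  On the constraint manifold (1/N) S^T S = I the loss is
bounded below by minus the top-K eigenvalue mean, with equality at the
scaled top-K eigenvectors; without the constraint the penalty trades off
against the trace, so the unconstrained minimum sits slightly lower, at
-(1/K) sum_k (lambda_k + lambda_k^2 / (4K))  (closed form, used as the
optimisation oracle in tests).
"""

from __future__ import annotations

import numpy as np

from ._tensor import Adam, Tensor, astensor
from .graph import CellGraph

__all__ = [
    "normalized_cut_score",
    "topk_eigsum",
    "sg_loss",
    "total_sg_loss",
    "sg_loss_tensor",
    "minimize_sg_loss",
    "unconstrained_optimum",
    "indicator_embedding",
]


def normalized_cut_score(graph: CellGraph, labels, K: int) -> float:
    """Discrete K-way normalized-cut association score on the binary adjacency."""
    A = graph.adjacency
    labels = np.asarray(labels)
    if labels.shape[0] != A.shape[0]:
        raise ValueError("labels length must match graph size")
    total = 0.0
    for k in range(K):
        members = labels == k
        if not members.any():
            raise ValueError(f"cluster {k} is empty")
        links = A[np.ix_(members, members)].sum()
        degree = A[members, :].sum()
        total += links / degree
    return float(total / K)


def topk_eigsum(graph: CellGraph, K: int) -> float:
    """Mean of the K largest eigenvalues of ``D^{-1/2} A D^{-1/2}``.

    This is the optimum of the spectrally relaxed normalized cut.
    """
    n = graph.n_cells
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    eigvals = np.linalg.eigvalsh(graph.degree_normalized_adjacency())
    return float(eigvals[-K:].sum() / K)


def _sg_terms(S: Tensor, B: np.ndarray, K: int) -> Tensor:
    n, d = S.shape
    gram = (S.T @ S) * (1.0 / n) - np.eye(d)
    penalty = (gram**2.0).sum()
    trace = (S * (astensor(B) @ S)).sum() * (1.0 / (n * K))
    return penalty - trace


def sg_loss_tensor(S: Tensor, graph: CellGraph, K: int) -> Tensor:
    """Differentiable structural-grouping loss as an autodiff node."""
    return _sg_terms(S, graph.degree_normalized_adjacency(), K)


def sg_loss(S: np.ndarray, graph: CellGraph, K: int) -> float:
    """Structural-grouping loss of one layer's assignment matrix ``S`` (N x d)."""
    S = np.asarray(S, dtype=np.float64)
    if not np.isfinite(S).all():
        raise ValueError("S contains non-finite entries")
    if S.ndim != 2 or S.shape[0] != graph.n_cells:
        raise ValueError("S must be N x d with N matching the graph")
    return float(sg_loss_tensor(Tensor(S), graph, K).item())


def total_sg_loss(S_list, graph: CellGraph, K: int) -> float:
    """Sum of per-layer structural-grouping losses."""
    S_list = list(S_list)
    if not S_list:
        raise ValueError("need at least one layer")
    return float(sum(sg_loss(S, graph, K) for S in S_list))


def indicator_embedding(graph: CellGraph, labels, K: int) -> np.ndarray:
    """Map a hard partition to its relaxed embedding ``sqrt(N) * E``.

    Columns are E_k = D^{1/2} F_k (F_k^T D F_k)^{-1/2}; plugged into
    :func:`sg_loss` the penalty vanishes and the trace term equals the
    discrete :func:`normalized_cut_score`.
    """
    labels = np.asarray(labels)
    n = graph.n_cells
    d_sqrt = np.sqrt(graph.degrees)
    E = np.zeros((n, K))
    for k in range(K):
        members = labels == k
        if not members.any():
            raise ValueError(f"cluster {k} is empty")
        col = np.where(members, d_sqrt, 0.0)
        E[:, k] = col / np.linalg.norm(col)
    return np.sqrt(n) * E


def unconstrained_optimum(graph: CellGraph, K: int) -> float:
    """Closed-form global minimum of :func:`sg_loss` over all N x K matrices.

    With eigenvalues lambda_1 >= ... of the degree-normalized adjacency, the
    optimum is -(1/K) sum_{k<=K} (lambda_k + lambda_k^2 / (4K)): the soft
    orthonormality penalty lets each direction overshoot unit scale by
    lambda/(2K), buying an extra lambda^2/(4K^2) per eigenvalue.
    """
    eigvals = np.linalg.eigvalsh(graph.degree_normalized_adjacency())[::-1][:K]
    return float(-(eigvals / K + eigvals**2 / (4 * K * K)).sum())


def minimize_sg_loss(graph: CellGraph, K: int, n_steps: int = 2000,
                     lr: float = 0.05, seed: int = 0) -> tuple[np.ndarray, float]:
    """Unconstrained gradient minimisation of the loss over S (Adam, seeded)."""
    rng = np.random.default_rng(seed)
    S = Tensor(rng.standard_normal((graph.n_cells, K)), requires_grad=True)
    B = graph.degree_normalized_adjacency()
    opt = Adam([S], lr=lr)
    for _ in range(n_steps):
        opt.zero_grad()
        loss = _sg_terms(S, B, K)
        loss.backward()
        opt.step()
    return S.data.copy(), float(_sg_terms(S, B, K).item())
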