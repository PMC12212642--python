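"""Decoupled self-supervised clustering signals.

Each channel (feature embedding z, structural embedding h) gets its own
cluster centres, its own Student-t soft assignment Q, and its own sharpened
target P; the two KL(P||Q) losses share no parameters, so each channel is
supervised by a signal derived from its own geometry ("decoupled").

    q_ij  =  (1 + ||z_i - c_j||^2)^-1  /  sum_k (1 + ||z_i - c_k||^2)^-1
    p_ij  =  (q_ij^2 / f_j) / sum_k (q_ik^2 / f_k),   f_j = sum_i q_ij

Squaring emphasises confident assignments and dividing by the cluster
frequency f_j counters the tendency of large clusters to absorb everything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, astensor

__all__ = [
    "ClusterDistributions",
    "init_centers",
    "soft_assign",
    "target_distribution",
    "kl_loss",
    "soft_assign_tensor",
    "kl_loss_tensor",
]


@dataclass
class ClusterDistributions:
    """Per-channel centres, soft assignments and sharpened targets."""

    centers_z: np.ndarray | None = None
    centers_h: np.ndarray | None = None
    Q_z: np.ndarray | None = None
    Q_h: np.ndarray | None = None
    P_z: np.ndarray | None = None
    P_h: np.ndarray | None = None


def init_centers(Z: np.ndarray, K: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """K-means initialisation of cluster centres (deterministic given seed)."""
    from sklearn.cluster import KMeans

    Z = np.asarray(Z, dtype=np.float64)
    if K > Z.shape[0]:
        raise ValueError(f"K={K} exceeds the number of points {Z.shape[0]}")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=int(seed))
    km.fit(Z)
    return km.cluster_centers_.astype(np.float64)


def soft_assign_tensor(Z: Tensor, centers: Tensor) -> Tensor:
    """Student-t (one degree of freedom) soft assignment as an autodiff node."""
    d2 = ((Z**2.0).sum(axis=1, keepdims=True)
          + ((centers**2.0).sum(axis=1, keepdims=True)).T
          - (Z @ centers.T) * 2.0)
    q = (d2 + 1.0) ** -1.0
    return q / q.sum(axis=1, keepdims=True)


def soft_assign(Z: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Row-stochastic N x K soft assignment of points to centres."""
    Z = np.asarray(Z, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    if Z.shape[1] != centers.shape[1]:
        raise ValueError("embedding and centre widths differ")
    return soft_assign_tensor(astensor(Z), astensor(centers)).data


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened, frequency-normalised target P from a soft assignment Q."""
    Q = np.asarray(Q, dtype=np.float64)
    f = Q.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(f > 0, Q**2 / f, 0.0)
    return W / W.sum(axis=1, keepdims=True)


def kl_loss(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) summed over cells and clusters, with 0 log 0 := 0."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same shape")
    support = P > 0
    if np.any(support & (Q <= 0)):
        raise ValueError("divergence: Q is zero where P has mass")
    val = np.sum(P[support] * np.log(P[support] / Q[support]))
    return float(max(val, 0.0)) if abs(val) < 1e-12 else float(val)


def kl_loss_tensor(P: np.ndarray, Q: Tensor) -> Tensor:
    """KL(P || Q) with P held constant (stop-gradient target)."""
    P = np.asarray(P, dtype=np.float64)
    entropy = float(np.sum(np.where(P > 0, P * np.log(np.maximum(P, 1e-300)), 0.0)))
    cross = (astensor(P) * Q.log()).sum()
    return entropy - cross
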