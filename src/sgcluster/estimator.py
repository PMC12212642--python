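"""Training orchestration and the scikit-learn clustering estimator.

Training proceeds in three phases, all full-batch Adam (the data are
desk-scale, thousands of cells):

1. pretrain the autoencoder on its reconstruction loss;
2. pretrain the graph-attention channel on the adjacency reconstruction
   loss (plus the structural-grouping term when enabled), with the AE
   frozen;
3. K-means-initialise one centre set per channel, then jointly minimise

       L = L_res + KL(P_z||Q_z) + alpha * L_SG + beta * KL(P_h||Q_h)

   refreshing the stop-gradient targets P every ``update_interval`` epochs
   and stopping early once fewer than ``stop_tol`` of the labels change
   between consecutive refreshes.

Final labels come from the structural channel's soft assignment Q_h by
default (it fuses both information sources), switchable to Q_z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._tensor import Adam, Tensor
from .graph import CellGraph, cell_graph
from .network import InteractiveNetwork
from .selfsup import (ClusterDistributions, init_centers, kl_loss_tensor,
                      soft_assign_tensor, target_distribution)
from .spectral import sg_loss_tensor

__all__ = ["TrainConfig", "LossParts", "FitResult", "overall_loss",
           "predict_labels", "train", "StructuralGroupingClustering"]


@dataclass
class TrainConfig:
    """Hyperparameters of the joint objective and its optimisation."""

    n_clusters: int
    hidden_dims: Sequence[int] = (256, 64, 16)
    alpha: float = 3e-5          # weight of the structural-grouping loss
    beta: float = 10.0           # weight of the structural-channel KL
    lr_pretrain: float = 1e-3
    lr_joint: float = 3e-5
    pretrain_epochs: int = 100
    joint_epochs: int = 200
    update_interval: int = 1     # target-distribution refresh cadence (epochs)
    stop_tol: float = 1e-3       # stop when < this fraction of labels change
    min_joint_epochs: int = 100  # burn-in before the stopping rule may fire
    sg_warmup: float = 1e-2      # L_SG weight during GATE pretraining
    label_channel: str = "h"     # which soft assignment yields labels
    use_res: bool = True
    use_ae: bool = True
    use_gate: bool = True
    use_sg: bool = True
    use_kl: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.label_channel not in ("z", "h"):
            raise ValueError("label_channel must be 'z' or 'h'")
        if not self.use_ae and not self.use_gate:
            raise ValueError("cannot disable both channels")


@dataclass
class LossParts:
    l_res: float = 0.0
    l_kl_z: float = 0.0
    l_sg: float = 0.0
    l_kl_h: float = 0.0


def overall_loss(parts: LossParts, cfg: TrainConfig) -> float:
    """Combine the four loss terms with the trade-off weights and ablation flags."""
    total = 0.0
    if cfg.use_res:
        total += parts.l_res
    if cfg.use_kl and cfg.use_ae:
        total += parts.l_kl_z
    if cfg.use_sg and cfg.use_gate:
        total += cfg.alpha * parts.l_sg
    if cfg.use_kl and cfg.use_gate:
        total += cfg.beta * parts.l_kl_h
    return float(total)


def predict_labels(dist: ClusterDistributions, channel: str = "h") -> np.ndarray:
    """Hard labels: row argmax of the chosen Q (lowest index wins ties)."""
    Q = dist.Q_h if channel == "h" else dist.Q_z
    if Q is None:
        raise ValueError(f"channel '{channel}' has no soft assignment")
    return np.argmax(Q, axis=1)


@dataclass
class FitResult:
    labels: np.ndarray
    embedding_z: np.ndarray | None
    embedding_h: np.ndarray | None
    history: pd.DataFrame
    distributions: ClusterDistributions
    config: TrainConfig


def _check_finite(value: float, term: str, epoch: int) -> float:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss term '{term}' at epoch {epoch}")
    return float(value)


def train(X: np.ndarray, graph: CellGraph, cfg: TrainConfig,
          y=None, verbose: bool = False) -> FitResult:
    """Run the full pretrain + joint optimisation and extract labels.

    ``y`` (optional ground truth) is used only to record ARI/NMI per epoch
    in the history; it never influences training.
    """
    from .metrics import ari as _ari, nmi as _nmi

    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if graph.n_cells != n:
        raise ValueError("graph and matrix disagree on the number of cells")
    rng = np.random.default_rng(cfg.seed)
    net = InteractiveNetwork(X.shape[1], cfg.hidden_dims, rng,
                             use_ae=cfg.use_ae, use_gate=cfg.use_gate)
    Xt = Tensor(X)
    K = cfg.n_clusters
    records: list[dict] = []

    def log(phase, epoch, **terms):
        records.append({"phase": phase, "epoch": epoch, **terms})
        if verbose:
            import sys

            msg = " ".join(f"{k}={v:.5g}" for k, v in terms.items())
            print(f"[{phase}] epoch {epoch}: {msg}", file=sys.stderr)

    # ------------------------------------------------------------ pretraining
    if cfg.use_ae:
        opt = Adam(net.ae_params(), lr=cfg.lr_pretrain)
        for epoch in range(1, cfg.pretrain_epochs + 1):
            opt.zero_grad()
            _, _, l_ae = net.ae_forward(Xt)
            _check_finite(l_ae.item(), "l_ae_res", epoch)
            l_ae.backward()
            opt.step()
            log("pretrain_ae", epoch, l_ae=l_ae.item())

    Z_fixed = None
    if cfg.use_ae:
        Z_layers, _, _ = net.ae_forward(Xt)
        Z_fixed = [z.detach() for z in Z_layers]  # AE frozen during GATE pretraining

    if cfg.use_gate:
        opt = Adam(net.gate_params(), lr=cfg.lr_pretrain)
        B = graph.degree_normalized_adjacency()
        for epoch in range(1, cfg.pretrain_epochs + 1):
            opt.zero_grad()
            out = net.forward(Xt, graph, Z_layers=Z_fixed)
            loss = out["l_gate"]
            if cfg.use_sg:
                loss = loss + cfg.sg_warmup * sum(
                    (sg_loss_tensor(S, graph, K) for S in out["S"]), Tensor(0.0)
                )
            _check_finite(loss.item(), "l_gate_res", epoch)
            loss.backward()
            opt.step()
            log("pretrain_gate", epoch, l_gate=out["l_gate"].item())

    # ------------------------------------------------- centre initialisation
    out = net.forward(Xt, graph if cfg.use_gate else None)
    z_emb = out["Z"][-1].data if cfg.use_ae else None
    h_emb = out["H"][-1].data if cfg.use_gate else None
    km_seed = int(rng.integers(2**31 - 1))
    centers_z = centers_h = None
    if cfg.use_kl:
        if cfg.use_ae:
            centers_z = Tensor(init_centers(z_emb, K, seed=km_seed), requires_grad=True)
        if cfg.use_gate:
            centers_h = Tensor(init_centers(h_emb, K, seed=km_seed), requires_grad=True)

    # ------------------------------------------------------------- joint phase
    dist = ClusterDistributions()
    labels_prev = None
    if cfg.use_kl:
        params = net.parameters()
        params += [c for c in (centers_z, centers_h) if c is not None]
        opt = Adam(params, lr=cfg.lr_joint)
        P_z = P_h = None
        for epoch in range(1, cfg.joint_epochs + 1):
            opt.zero_grad()
            out = net.forward(Xt, graph if cfg.use_gate else None)
            q_z_t = (soft_assign_tensor(out["Z"][-1], centers_z)
                     if cfg.use_ae else None)
            q_h_t = (soft_assign_tensor(out["H"][-1], centers_h)
                     if cfg.use_gate else None)

            if (epoch - 1) % cfg.update_interval == 0:
                P_z = target_distribution(q_z_t.data) if q_z_t is not None else None
                P_h = target_distribution(q_h_t.data) if q_h_t is not None else None
                q_now = q_h_t if (cfg.label_channel == "h" and q_h_t is not None) else q_z_t
                labels_now = np.argmax(q_now.data, axis=1)
                if labels_prev is not None and epoch > cfg.min_joint_epochs:
                    delta = float(np.mean(labels_now != labels_prev))
                    if delta < cfg.stop_tol:
                        labels_prev = labels_now
                        break
                labels_prev = labels_now

            parts = LossParts()
            loss = Tensor(0.0)
            parts.l_res = _check_finite(out["l_ae"].item() + out["l_gate"].item(),
                                        "l_res", epoch)
            if cfg.use_res:
                loss = loss + out["l_ae"] + out["l_gate"]
            if cfg.use_ae:
                t = kl_loss_tensor(P_z, q_z_t)
                parts.l_kl_z = _check_finite(t.item(), "l_kl_z", epoch)
                loss = loss + t
            if cfg.use_gate and cfg.use_sg:
                t = sum((sg_loss_tensor(S, graph, K) for S in out["S"]), Tensor(0.0))
                parts.l_sg = _check_finite(t.item(), "l_sg", epoch)
                loss = loss + cfg.alpha * t
            if cfg.use_gate:
                t = kl_loss_tensor(P_h, q_h_t)
                parts.l_kl_h = _check_finite(t.item(), "l_kl_h", epoch)
                loss = loss + cfg.beta * t
            total = overall_loss(parts, cfg)
            row = {"l_res": parts.l_res, "l_kl_z": parts.l_kl_z,
                   "l_sg": parts.l_sg, "l_kl_h": parts.l_kl_h, "total": total}
            if y is not None:
                q_now = q_h_t if (cfg.label_channel == "h" and q_h_t is not None) else q_z_t
                lab = np.argmax(q_now.data, axis=1)
                row["ari"] = _ari(y, lab)
                row["nmi"] = _nmi(y, lab)
            log("joint", epoch, **row)
            loss.backward()
            opt.step()

    # --------------------------------------------------------------- wrap up
    out = net.forward(Xt, graph if cfg.use_gate else None)
    z_emb = out["Z"][-1].data if cfg.use_ae else None
    h_emb = out["H"][-1].data if cfg.use_gate else None
    if cfg.use_kl:
        dist.centers_z = centers_z.data if centers_z is not None else None
        dist.centers_h = centers_h.data if centers_h is not None else None
        if cfg.use_ae:
            dist.Q_z = soft_assign_tensor(Tensor(z_emb), centers_z.detach()).data
            dist.P_z = target_distribution(dist.Q_z)
        if cfg.use_gate:
            dist.Q_h = soft_assign_tensor(Tensor(h_emb), centers_h.detach()).data
            dist.P_h = target_distribution(dist.Q_h)
        channel = cfg.label_channel
        if channel == "h" and dist.Q_h is None:
            channel = "z"
        if channel == "z" and dist.Q_z is None:
            channel = "h"
        labels = predict_labels(dist, channel)
    else:
        # ablation: no self-supervision; cluster the learned embedding directly
        emb = h_emb if (cfg.label_channel == "h" and h_emb is not None) else z_emb
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=K, n_init=10,
                        random_state=km_seed).fit_predict(emb)
    if not records:
        log("final", 0, note=0.0)
    history = pd.DataFrame.from_records(records)
    return FitResult(labels=np.asarray(labels), embedding_z=z_emb,
                     embedding_h=h_emb, history=history,
                     distributions=dist, config=cfg)


# --------------------------------------------------------------------- sklearn

try:  # BaseEstimator gives get_params/set_params/clone support
    from sklearn.base import BaseEstimator, ClusterMixin
except ImportError:  # pragma: no cover
    BaseEstimator = ClusterMixin = object


class StructuralGroupingClustering(ClusterMixin, BaseEstimator):
    """Deep graph clustering of cells with a differentiable normalized-cut loss.

    Expects a preprocessed (normalised, log-transformed) cells x genes
    matrix; builds the denoised KNN cell-cell graph internally, trains the
    fused AE/graph-attention model, and exposes the final labels and both
    embeddings.

    Parameters mirror :class:`TrainConfig` plus the graph-construction knobs
    (``knn`` neighbours, ``ne_neighbors``/``ne_iters`` for the
    network-enhancement diffusion).  ``random_state`` seeds every source of
    randomness, so fits are reproducible bit-for-bit.

    Attributes (after ``fit``)
    --------------------------
    labels_ : (N,) int array of cluster assignments
    embedding_z_, embedding_h_ : final feature / structural embeddings
    graph_ : the :class:`CellGraph` used for training
    history_ : per-epoch loss (and metric, if ``y`` was passed) records
    """

    def __init__(self, n_clusters: int = 2, knn: int = 15,
                 ne_neighbors: int | None = None, ne_iters: int = 2,
                 enhance: bool = True, hidden_dims: Sequence[int] = (256, 64, 16),
                 alpha: float = 3e-5, beta: float = 10.0,
                 lr_pretrain: float = 1e-3, lr_joint: float = 3e-5,
                 pretrain_epochs: int = 100, joint_epochs: int = 200,
                 update_interval: int = 1, stop_tol: float = 1e-3,
                 min_joint_epochs: int = 100, sg_warmup: float = 1e-2,
                 label_channel: str = "h", use_res: bool = True,
                 use_ae: bool = True, use_gate: bool = True,
                 use_sg: bool = True, use_kl: bool = True,
                 random_state: int = 0, verbose: bool = False):
        self.n_clusters = n_clusters
        self.knn = knn
        self.ne_neighbors = ne_neighbors
        self.ne_iters = ne_iters
        self.enhance = enhance
        self.hidden_dims = hidden_dims
        self.alpha = alpha
        self.beta = beta
        self.lr_pretrain = lr_pretrain
        self.lr_joint = lr_joint
        self.pretrain_epochs = pretrain_epochs
        self.joint_epochs = joint_epochs
        self.update_interval = update_interval
        self.stop_tol = stop_tol
        self.min_joint_epochs = min_joint_epochs
        self.sg_warmup = sg_warmup
        self.label_channel = label_channel
        self.use_res = use_res
        self.use_ae = use_ae
        self.use_gate = use_gate
        self.use_sg = use_sg
        self.use_kl = use_kl
        self.random_state = random_state
        self.verbose = verbose

    def _config(self) -> TrainConfig:
        return TrainConfig(
            n_clusters=self.n_clusters, hidden_dims=tuple(self.hidden_dims),
            alpha=self.alpha, beta=self.beta, lr_pretrain=self.lr_pretrain,
            lr_joint=self.lr_joint, pretrain_epochs=self.pretrain_epochs,
            joint_epochs=self.joint_epochs, update_interval=self.update_interval,
            stop_tol=self.stop_tol, min_joint_epochs=self.min_joint_epochs,
            sg_warmup=self.sg_warmup, label_channel=self.label_channel,
            use_res=self.use_res, use_ae=self.use_ae, use_gate=self.use_gate,
            use_sg=self.use_sg, use_kl=self.use_kl,
            seed=int(self.random_state or 0),
        )

    def fit(self, X, y=None):
        """Fit on a preprocessed cells x genes matrix.

        ``y`` is optional ground truth used purely for per-epoch ARI/NMI
        monitoring in ``history_``.
        """
        try:
            from sklearn.utils.validation import check_array

            X = check_array(X, dtype=np.float64)
        except ImportError:  # pragma: no cover
            X = np.asarray(X, dtype=np.float64)
        knn = min(self.knn, X.shape[0] - 1)
        self.graph_ = cell_graph(X, k=knn, k_ne=self.ne_neighbors,
                                 n_iter=self.ne_iters, enhance=self.enhance)
        result = train(X, self.graph_, self._config(), y=y, verbose=self.verbose)
        self.labels_ = result.labels
        self.embedding_z_ = result.embedding_z
        self.embedding_h_ = result.embedding_h
        self.history_ = result.history
        self.distributions_ = result.distributions
        self.result_ = result
        self.n_features_in_ = X.shape[1]
        return self
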