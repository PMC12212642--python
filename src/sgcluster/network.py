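"""The interactive dual-channel network: autoencoder + graph attention autoencoder.

Two encoders of equal depth run side by side.  The autoencoder (AE) channel
captures per-cell feature structure; the graph-attention (GATE) channel
aggregates each cell's neighbourhood with learned softmax attention over the
cell-cell graph.  After every shared layer r < L the AE representation is
fused additively into the GATE stream, U(r) = Z(r) + H(r), so the structural
channel is continually re-anchored to the feature channel (the layer-wise
answer to the feature/structure "heterogeneous gap").  The AE decoder
reconstructs the expression matrix (MSE); the GATE decoder reconstructs the
adjacency through a sigmoid gram matrix of the final structural embedding.

Each GATE layer's pre-activation S(l) = att . (U(l-1) W(l)^T) doubles as the
relaxed cluster-assignment matrix fed to the structural-grouping loss.

The class operates on autodiff tensors; the module-level functions are the
NumPy reference API used for testing individual operations.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, astensor, masked_row_softmax
from .graph import CellGraph

__all__ = [
    "InteractiveNetwork",
    "attention_scores",
    "gate_layer",
    "fuse",
    "decode_graph",
    "reconstruction_loss",
]

LEAKY_SLOPE = 0.2  # GAT convention


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


class InteractiveNetwork:
    """Parameters and forward pass of the fused AE/GATE model.

    Parameters are ``Tensor`` objects with ``requires_grad=True``; the
    forward pass returns every per-layer activation the losses need.
    """

    def __init__(self, n_features: int, hidden_dims=(256, 64, 16),
                 rng: np.random.Generator | None = None,
                 use_ae: bool = True, use_gate: bool = True,
                 gate_init_scale: float = 0.1):
        if not use_ae and not use_gate:
            raise ValueError("at least one of the AE / GATE channels must be enabled")
        rng = rng or np.random.default_rng(0)
        self.dims = [int(n_features), *map(int, hidden_dims)]
        self.n_layers = len(self.dims) - 1
        self.use_ae = use_ae
        self.use_gate = use_gate

        def param(arr):
            return Tensor(arr, requires_grad=True)

        self.enc_W, self.enc_b, self.dec_W, self.dec_b = [], [], [], []
        if use_ae:
            for l in range(self.n_layers):
                self.enc_W.append(param(_glorot(rng, self.dims[l + 1], self.dims[l])))
                self.enc_b.append(param(np.zeros((1, self.dims[l + 1]))))
            rev = self.dims[::-1]
            for l in range(self.n_layers):
                self.dec_W.append(param(_glorot(rng, rev[l + 1], rev[l])))
                self.dec_b.append(param(np.zeros((1, rev[l + 1]))))

        self.gat_W, self.gat_a_src, self.gat_a_dst = [], [], []
        if use_gate:
            # damped init keeps the sigmoid-gram decoder out of saturation
            for l in range(self.n_layers):
                self.gat_W.append(param(gate_init_scale
                                        * _glorot(rng, self.dims[l + 1], self.dims[l])))
                self.gat_a_src.append(param(_glorot(rng, self.dims[l + 1], 1).T * 0.1))
                self.gat_a_dst.append(param(_glorot(rng, self.dims[l + 1], 1).T * 0.1))

    # ------------------------------------------------------------------ params
    def ae_params(self) -> list[Tensor]:
        return [*self.enc_W, *self.enc_b, *self.dec_W, *self.dec_b]

    def gate_params(self) -> list[Tensor]:
        return [*self.gat_W, *self.gat_a_src, *self.gat_a_dst]

    def parameters(self) -> list[Tensor]:
        return self.ae_params() + self.gate_params()

    # ------------------------------------------------------------------ forward
    def ae_forward(self, X: Tensor) -> tuple[list[Tensor], Tensor, Tensor]:
        """Encode/decode the feature channel; returns (Z layers, X_hat, MSE loss).

        Hidden layers use ReLU; the latent layer and the output layer are
        linear (standard for embedding autoencoders).
        """
        Z_layers: list[Tensor] = []
        h = X
        for l in range(self.n_layers):
            h = h @ self.enc_W[l].T + self.enc_b[l]
            if l < self.n_layers - 1:
                h = h.relu()
            Z_layers.append(h)
        out = h
        for l in range(self.n_layers):
            out = out @ self.dec_W[l].T + self.dec_b[l]
            if l < self.n_layers - 1:
                out = out.relu()
        loss = ((X - out) ** 2.0).mean()
        return Z_layers, out, loss

    def gate_layer_forward(self, U_prev: Tensor, mask: np.ndarray, layer: int
                           ) -> tuple[Tensor, Tensor, Tensor]:
        """One attention layer; returns (att, S pre-activation, H = ReLU(S))."""
        Wh = U_prev @ self.gat_W[layer].T
        e_src = Wh @ self.gat_a_src[layer].T        # (N, 1)
        e_dst = Wh @ self.gat_a_dst[layer].T        # (N, 1)
        logits = (e_src + e_dst.T).leaky_relu(LEAKY_SLOPE)
        att = masked_row_softmax(logits, mask)
        S = att @ Wh
        return att, S, S.relu()

    def forward(self, X: Tensor, graph: CellGraph | None,
                Z_layers: list[Tensor] | None = None) -> dict:
        """Full fused forward pass.

        ``Z_layers`` may be supplied pre-computed (e.g. detached constants
        during GATE pretraining); otherwise the AE runs too.  Returns a dict
        with per-layer activations and both reconstruction losses.
        """
        out: dict = {}
        if self.use_ae:
            if Z_layers is None:
                Z_layers, X_hat, l_ae = self.ae_forward(X)
                out["X_hat"] = X_hat
            else:
                l_ae = Tensor(0.0)
            out["Z"] = Z_layers
            out["l_ae"] = l_ae
        else:
            Z_layers = None
            out["l_ae"] = Tensor(0.0)

        if self.use_gate:
            if graph is None:
                raise ValueError("the GATE channel requires a cell graph")
            mask = graph.neighbor_mask()
            att_layers, S_layers, H_layers = [], [], []
            U = X
            for l in range(self.n_layers):
                att, S, H = self.gate_layer_forward(U, mask, l)
                att_layers.append(att)
                S_layers.append(S)
                H_layers.append(H)
                if l < self.n_layers - 1:
                    U = Z_layers[l] + H if (self.use_ae and Z_layers is not None) else H
            H_final = H_layers[-1]
            A_hat = (H_final @ H_final.T).sigmoid()
            l_gate = ((astensor(graph.adjacency) - A_hat) ** 2.0).mean()
            out.update(att=att_layers, S=S_layers, H=H_layers,
                       A_hat=A_hat, l_gate=l_gate)
        else:
            out["l_gate"] = Tensor(0.0)
        return out


# ----------------------------------------------------------- NumPy reference API

def attention_scores(H_in: np.ndarray, graph: CellGraph, a: np.ndarray,
                     W: np.ndarray) -> np.ndarray:
    """Dense N x N attention matrix: softmax over each cell's neighbourhood of
    LeakyReLU(a^T [W h_i || W h_j]); zero off-graph, rows sum to 1."""
    H_in = np.asarray(H_in, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64).ravel()
    d = W.shape[0]
    if a.shape[0] != 2 * d:
        raise ValueError("attention vector must have length 2 * output width")
    Wh = H_in @ W.T
    # e_ij = a_src . (W h_i) + a_dst . (W h_j)
    e = (Wh @ a[:d])[:, None] + (Wh @ a[d:])[None, :]
    e = np.where(e > 0, e, LEAKY_SLOPE * e)
    mask = graph.neighbor_mask()
    z = np.where(mask, e, -np.inf)
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z, where=np.isfinite(z), out=np.zeros_like(z))
    return p / p.sum(axis=1, keepdims=True)


def gate_layer(U_prev: np.ndarray, graph: CellGraph, a: np.ndarray,
               W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NumPy reference of one GATE layer: S = att . (U_prev W^T), H = ReLU(S)."""
    U_prev = np.asarray(U_prev, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if U_prev.shape[1] != W.shape[1]:
        raise ValueError(f"width mismatch: U has {U_prev.shape[1]} columns, "
                         f"W expects {W.shape[1]}")
    att = attention_scores(U_prev, graph, a, W)
    S = att @ (U_prev @ W.T)
    return S, np.maximum(S, 0.0)


def fuse(Z_r: np.ndarray, H_r: np.ndarray) -> np.ndarray:
    """Layer-wise additive fusion U(r) = Z(r) + H(r)."""
    Z_r, H_r = np.asarray(Z_r), np.asarray(H_r)
    if Z_r.shape != H_r.shape:
        raise ValueError(f"shape mismatch: {Z_r.shape} vs {H_r.shape}")
    return Z_r + H_r


def decode_graph(H_L: np.ndarray, graph: CellGraph) -> tuple[np.ndarray, float]:
    """Inner-product decoder: A_hat = sigmoid(H H^T); returns (A_hat, MSE vs A)."""
    H_L = np.asarray(H_L, dtype=np.float64)
    A_hat = 1.0 / (1.0 + np.exp(-(H_L @ H_L.T)))
    loss = float(((graph.adjacency - A_hat) ** 2).mean())
    return A_hat, loss


def reconstruction_loss(l_ae_res: float, l_gate_res: float) -> float:
    """Total reconstruction loss of the interactive module."""
    if not (np.isfinite(l_ae_res) and np.isfinite(l_gate_res)):
        raise ValueError("reconstruction losses must be finite")
    return float(l_ae_res) + float(l_gate_res)
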