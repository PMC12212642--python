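"""Interactive AE/GATE model: attention, fusion, decoders, reference parity."""

import numpy as np
import pytest

from sgcluster._tensor import Tensor
from sgcluster.network import (InteractiveNetwork, attention_scores, decode_graph,
                               fuse, gate_layer, reconstruction_loss)

from conftest import graph_from_adjacency, random_graph


def dense_attention_oracle(H, graph, a, W, slope=0.2):
    """Double-loop evaluation of the attention definition."""
    n, d = H.shape[0], W.shape[0]
    att = np.zeros((n, n))
    Wh = H @ W.T
    for i in range(n):
        nbrs = np.flatnonzero(graph.adjacency[i] > 0)
        logits = []
        for j in nbrs:
            e = a[:d] @ Wh[i] + a[d:] @ Wh[j]
            logits.append(e if e > 0 else slope * e)
        logits = np.array(logits)
        w = np.exp(logits - logits.max())
        att[i, nbrs] = w / w.sum()
    return att


class TestAttention:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.g = random_graph(5, 0.5, seed=0)
        self.H = rng.standard_normal((5, 4))
        self.W = rng.standard_normal((3, 4))
        self.a = rng.standard_normal(6)

    def test_matches_dense_loop_oracle(self):
        att = attention_scores(self.H, self.g, self.a, self.W)
        oracle = dense_attention_oracle(self.H, self.g, self.a, self.W)
        assert np.allclose(att, oracle, atol=1e-10)

    def test_rows_sum_to_one_on_neighborhoods(self):
        att = attention_scores(self.H, self.g, self.a, self.W)
        assert np.allclose(att.sum(axis=1), 1.0, atol=1e-12)
        assert (att[self.g.adjacency == 0] == 0).all()

    def test_singleton_neighborhood_gets_weight_one(self):
        g = graph_from_adjacency(np.zeros((3, 3)))  # only self-loops
        att = attention_scores(self.H[:3], g, self.a, self.W)
        assert np.allclose(att, np.eye(3))

    def test_identical_features_give_uniform_attention(self):
        H = np.tile(self.H[0], (5, 1))
        att = attention_scores(H, self.g, self.a, self.W)
        sizes = self.g.adjacency.sum(axis=1)
        expected = self.g.adjacency / sizes[:, None]
        assert np.allclose(att, expected, atol=1e-12)


class TestGateLayer:
    def test_zero_input_gives_zero_output(self):
        g = random_graph(4, 0.6, seed=1)
        rng = np.random.default_rng(1)
        S, H = gate_layer(np.zeros((4, 3)), g, rng.standard_normal(4),
                          rng.standard_normal((2, 3)))
        assert np.all(S == 0) and np.all(H == 0)

    def test_h_nonnegative_and_matches_dense_product(self):
        g = random_graph(5, 0.5, seed=2)
        rng = np.random.default_rng(2)
        U = rng.standard_normal((5, 4))
        W = rng.standard_normal((3, 4))
        a = rng.standard_normal(6)
        S, H = gate_layer(U, g, a, W)
        assert (H >= 0).all()
        att = dense_attention_oracle(U, g, a, W)
        assert np.allclose(S, att @ (U @ W.T), atol=1e-10)

    def test_width_mismatch_rejected(self):
        g = random_graph(4, 0.5, seed=3)
        with pytest.raises(ValueError):
            gate_layer(np.zeros((4, 3)), g, np.zeros(4), np.zeros((2, 5)))


class TestFuse:
    def test_additive_identity_commutativity_inverse(self):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((4, 3))
        H = rng.standard_normal((4, 3))
        assert np.array_equal(fuse(Z, np.zeros_like(Z)), Z)
        assert np.array_equal(fuse(Z, H), fuse(H, Z))
        assert np.all(fuse(Z, -Z) == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros((3, 2)), np.zeros((2, 3)))


class TestGraphDecoder:
    def test_symmetric_and_bounded(self):
        g = random_graph(6, 0.5, seed=5)
        H = np.random.default_rng(5).standard_normal((6, 3))
        A_hat, loss = decode_graph(H, g)
        assert np.allclose(A_hat, A_hat.T)
        assert ((A_hat > 0) & (A_hat < 1)).all()
        assert loss >= 0

    def test_zero_embedding_gives_half_everywhere(self):
        g = random_graph(6, 0.5, seed=6)
        A_hat, loss = decode_graph(np.zeros((6, 2)), g)
        assert np.allclose(A_hat, 0.5)
        assert loss == pytest.approx(((g.adjacency - 0.5) ** 2).mean())


def test_reconstruction_loss_is_the_sum():
    assert reconstruction_loss(0.0, 0.0) == 0.0
    assert reconstruction_loss(0.3, 0.0) == pytest.approx(0.3)
    assert reconstruction_loss(0.25, 1.5) == pytest.approx(0.25 + 1.5)
    with pytest.raises(ValueError):
        reconstruction_loss(np.nan, 0.0)


class TestInteractiveNetwork:
    def test_ae_loss_nonnegative_and_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.random((12, 6))
        net1 = InteractiveNetwork(6, (4, 2), np.random.default_rng(0))
        net2 = InteractiveNetwork(6, (4, 2), np.random.default_rng(0))
        Z1, _, l1 = net1.ae_forward(Tensor(X))
        Z2, _, l2 = net2.ae_forward(Tensor(X))
        assert l1.item() >= 0
        assert l1.item() == l2.item()
        for a, b in zip(Z1, Z2):
            assert np.array_equal(a.data, b.data)

    def test_identity_autoencoder_reconstructs_exactly(self):
        net = InteractiveNetwork(2, (2,), np.random.default_rng(0))
        net.enc_W[0].data = np.eye(2)
        net.dec_W[0].data = np.eye(2)
        X = np.array([[0.5, 1.0], [2.0, 0.25]])
        _, X_hat, loss = net.ae_forward(Tensor(X))
        assert np.allclose(X_hat.data, X)
        assert loss.item() == pytest.approx(0.0, abs=1e-30)

    def test_forward_attention_matches_reference(self):
        g = random_graph(6, 0.5, seed=8)
        rng = np.random.default_rng(8)
        X = rng.random((6, 5))
        net = InteractiveNetwork(5, (3, 2), np.random.default_rng(1))
        out = net.forward(Tensor(X), g)
        # layer 0 attention from the raw input
        a0 = np.concatenate([net.gat_a_src[0].data.ravel(),
                             net.gat_a_dst[0].data.ravel()])
        ref = attention_scores(X, g, a0, net.gat_W[0].data)
        assert np.allclose(out["att"][0].data, ref, atol=1e-10)
        # every layer's attention rows sum to one
        for att in out["att"]:
            assert np.allclose(att.data.sum(axis=1), 1.0, atol=1e-8)

    def test_fusion_feeds_next_layer(self):
        # with AE disabled the second layer sees H(1); with AE it sees Z(1)+H(1)
        g = random_graph(6, 0.6, seed=9)
        X = np.random.default_rng(9).random((6, 5))
        net = InteractiveNetwork(5, (3, 2), np.random.default_rng(2))
        out = net.forward(Tensor(X), g)
        Z1, H1 = out["Z"][0].data, out["H"][0].data
        U1 = Z1 + H1
        a1 = np.concatenate([net.gat_a_src[1].data.ravel(),
                             net.gat_a_dst[1].data.ravel()])
        S_ref, _ = gate_layer(U1, g, a1, net.gat_W[1].data)
        assert np.allclose(out["S"][1].data, S_ref, atol=1e-10)
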