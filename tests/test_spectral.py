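"""Normalized cut: discrete score, spectral relaxation, differentiable loss."""

import itertools

import numpy as np
import pytest

from sgcluster.spectral import (indicator_embedding, minimize_sg_loss,
                                normalized_cut_score, sg_loss, topk_eigsum,
                                total_sg_loss, unconstrained_optimum)

from conftest import block_graph, graph_from_adjacency, random_graph


def brute_force_score(graph, labels, K):
    """Direct double sum over all (i, j) pairs of the cut objective."""
    A = graph.adjacency
    total = 0.0
    for k in range(K):
        links = sum(A[i, j] for i in range(len(labels)) for j in range(len(labels))
                    if labels[i] == k and labels[j] == k)
        degree = sum(A[i, j] for i in range(len(labels)) for j in range(len(labels))
                     if labels[i] == k)
        total += links / degree
    return total / K


class TestNormalizedCutScore:
    def test_disconnected_triangles_perfect_partition(self):
        g = block_graph([3, 3])
        assert normalized_cut_score(g, [0, 0, 0, 1, 1, 1], 2) == pytest.approx(1.0)

    def test_single_cluster_scores_one(self):
        g = random_graph(7, 0.5, seed=0)
        assert normalized_cut_score(g, np.zeros(7, dtype=int), 1) == pytest.approx(1.0)

    def test_matches_brute_force_double_sum(self):
        g = graph_from_adjacency(1 - np.eye(4))  # complete K4 (self-loops added)
        labels = np.array([0, 0, 1, 1])
        assert normalized_cut_score(g, labels, 2) == pytest.approx(
            brute_force_score(g, labels, 2), abs=1e-12)
        g2 = random_graph(6, 0.6, seed=4)
        labels2 = np.array([0, 1, 0, 2, 1, 2])
        assert normalized_cut_score(g2, labels2, 3) == pytest.approx(
            brute_force_score(g2, labels2, 3), abs=1e-12)

    def test_empty_cluster_rejected(self):
        g = random_graph(5, 0.5, seed=1)
        with pytest.raises(ValueError, match="cluster 2"):
            normalized_cut_score(g, [0, 0, 1, 1, 1], 3)


class TestTopkEigsum:
    def test_disjoint_components_score_one(self):
        for sizes in ([3, 4], [2, 3, 4]):
            g = block_graph(sizes)
            assert topk_eigsum(g, len(sizes)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_full_eigendecomposition(self):
        g = random_graph(9, 0.4, seed=2)
        eig = np.linalg.eigvalsh(g.degree_normalized_adjacency())
        for K in (1, 3, 9):
            assert topk_eigsum(g, K) == pytest.approx(eig[-K:].sum() / K, abs=1e-12)

    def test_partial_sums_concave_in_k(self):
        # sums of a sorted-descending eigenvalue list have non-increasing
        # increments (the list may contain negative eigenvalues)
        g = random_graph(10, 0.5, seed=3)
        sums = [K * topk_eigsum(g, K) for K in range(1, 11)]
        increments = np.diff(sums)
        assert all(b <= a + 1e-12 for a, b in zip(increments, increments[1:]))
        assert sums[0] == pytest.approx(1.0)  # top eigenvalue of the walk matrix

    def test_k_out_of_range(self):
        g = random_graph(5, 0.5, seed=1)
        with pytest.raises(ValueError):
            topk_eigsum(g, 6)


class TestSgLoss:
    def test_zero_matrix_gives_width(self):
        g = random_graph(8, 0.5, seed=0)
        for d in (1, 2, 5):
            assert sg_loss(np.zeros((8, d)), g, 3) == pytest.approx(float(d))

    def test_scaled_eigenvectors_attain_fan_bound(self):
        g = random_graph(10, 0.4, seed=5)
        K = 3
        B = g.degree_normalized_adjacency()
        _, vecs = np.linalg.eigh(B)
        S = np.sqrt(10) * vecs[:, -K:]
        assert sg_loss(S, g, K) == pytest.approx(-topk_eigsum(g, K), abs=1e-10)

    def test_gradient_minimization_reaches_closed_form_optimum(self):
        # two disconnected components, K=2: optimum has a closed form
        g = block_graph([6, 6])
        _, val = minimize_sg_loss(g, 2, n_steps=3000, lr=0.05, seed=1)
        assert val == pytest.approx(unconstrained_optimum(g, 2), abs=1e-2)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        g = random_graph(9, 0.5, seed=6)
        S = rng.standard_normal((9, 3))
        O, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert sg_loss(S @ O, g, 4) == pytest.approx(sg_loss(S, g, 4), abs=1e-10)

    def test_nonfinite_rejected(self):
        g = random_graph(5, 0.5, seed=1)
        S = np.ones((5, 2))
        S[0, 0] = np.nan
        with pytest.raises(ValueError):
            sg_loss(S, g, 2)


class TestTotalSgLoss:
    def test_additivity(self):
        rng = np.random.default_rng(7)
        g = random_graph(8, 0.5, seed=7)
        layers = [rng.standard_normal((8, d)) for d in (4, 3, 2)]
        assert total_sg_loss(layers[:1], g, 2) == pytest.approx(sg_loss(layers[0], g, 2))
        assert total_sg_loss(layers[:1] * 2, g, 2) == pytest.approx(
            2 * sg_loss(layers[0], g, 2))
        assert total_sg_loss(layers, g, 2) == pytest.approx(
            sum(sg_loss(S, g, 2) for S in layers))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            total_sg_loss([], random_graph(5, 0.5, seed=0), 2)


class TestRelaxationProperties:
    def test_fan_lower_bound_on_constraint_manifold(self):
        # any S with (1/N) S^T S = I obeys sg_loss >= -topk_eigsum
        for seed, n in [(0, 8), (1, 11), (2, 15)]:
            g = random_graph(n, 0.45, seed=seed)
            rng = np.random.default_rng(seed + 100)
            K = 3
            Q, _ = np.linalg.qr(rng.standard_normal((n, K)))
            S = np.sqrt(n) * Q
            assert sg_loss(S, g, K) >= -topk_eigsum(g, K) - 1e-9

    def test_hard_partition_embedding_reproduces_discrete_score(self):
        g = random_graph(7, 0.5, seed=9)
        labels = np.array([0, 1, 0, 1, 1, 0, 1])
        S = indicator_embedding(g, labels, 2)
        assert sg_loss(S, g, 2) == pytest.approx(
            -normalized_cut_score(g, labels, 2), abs=1e-10)

    def test_relaxed_optimum_dominates_all_discrete_partitions(self):
        # brute-force enumeration of every 2-partition of a 7-node graph
        g = random_graph(7, 0.5, seed=11)
        bound = topk_eigsum(g, 2)
        best = -np.inf
        for bits in itertools.product([0, 1], repeat=6):
            labels = np.array([0, *bits])
            if labels.max() == 0:
                continue
            best = max(best, normalized_cut_score(g, labels, 2))
        assert best <= bound + 1e-9
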