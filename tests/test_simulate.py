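"""Ground-truth generator: graph topology, precision construction,
Gaussian sampling and prior-corruption conventions."""

import numpy as np
import pytest

from dwglasso import (
    build_precision_matrix,
    corrupt_weight_matrix,
    generate_scale_free_graph,
    generate_two_group_data,
    sample_data,
)


class TestScaleFreeGraph:
    @pytest.mark.parametrize("p", [3, 10, 100, 500])
    def test_tree_density_is_2_over_p(self, p):
        adj = generate_scale_free_graph(p, seed=0)
        n_edges = np.triu(adj, k=1).sum()
        assert n_edges == p - 1
        assert n_edges / (p * (p - 1) / 2) == pytest.approx(2 / p)

    def test_connected_and_heavy_tailed(self):
        import networkx as nx

        adj = generate_scale_free_graph(200, seed=3)
        g = nx.from_numpy_array(adj)
        assert nx.is_connected(g)
        deg = adj.sum(axis=0)
        # preferential attachment produces hubs well above the mean degree
        assert deg.max() >= 8

    def test_deterministic_given_seed(self):
        a = generate_scale_free_graph(50, seed=7)
        b = generate_scale_free_graph(50, seed=7)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, generate_scale_free_graph(50, seed=8))

    def test_rejects_tiny_p(self):
        with pytest.raises(ValueError):
            generate_scale_free_graph(2, seed=0)


class TestPrecisionMatrix:
    def test_empty_adjacency_gives_identity_covariance(self):
        truth = build_precision_matrix(np.zeros((4, 4), dtype=int))
        assert np.allclose(truth.sigma, np.eye(4))
        assert np.allclose(truth.theta, np.diag(np.diag(truth.theta)))

    def test_positive_definite_and_support_preserved(self):
        adj = generate_scale_free_graph(40, seed=5)
        truth = build_precision_matrix(adj)
        assert np.linalg.eigvalsh(truth.theta)[0] > 0
        off = np.abs(truth.theta - np.diag(np.diag(truth.theta)))
        assert np.array_equal((off > 1e-10).astype(int), adj)
        assert np.allclose(np.diag(truth.sigma), 1.0)

    def test_path_graph_against_dense_eigensolver(self):
        # independent construction: explicit inverse route via eigh
        p, v, u = 5, 0.3, 0.1
        adj = np.zeros((p, p), dtype=int)
        for i in range(p - 1):
            adj[i, i + 1] = adj[i + 1, i] = 1
        truth = build_precision_matrix(adj, v=v, u=u)
        omega = v * adj.astype(float)
        w_eig, V = np.linalg.eigh(omega)
        np.fill_diagonal(omega, abs(w_eig[0]) + 0.1 + u)
        sigma_raw = np.linalg.inv(omega)
        d = np.sqrt(np.diag(sigma_raw))
        sigma = sigma_raw / np.outer(d, d)
        assert np.allclose(truth.sigma, sigma, atol=1e-12)
        assert np.allclose(truth.theta, np.linalg.inv(sigma), atol=1e-8)
        off_support = np.abs(truth.theta) > 1e-10
        np.fill_diagonal(off_support, False)
        assert np.array_equal(off_support.astype(int), adj)

    def test_rejects_asymmetric_input(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = 1
        with pytest.raises(ValueError):
            build_precision_matrix(adj)

    def test_theta_sigma_are_inverses(self, small_truth):
        assert np.allclose(small_truth.theta @ small_truth.sigma, np.eye(small_truth.p), atol=1e-8)


class TestSampleData:
    def test_columns_centered_and_unit_sum_of_squares(self, small_truth):
        X = sample_data(small_truth.sigma, 40, seed=2)
        assert np.allclose(X.sum(axis=0), 0, atol=1e-10)
        assert np.allclose((X**2).sum(axis=0), 1, atol=1e-10)

    def test_identity_covariance_gives_near_zero_correlations(self):
        X = sample_data(np.eye(5), 10000, seed=3)
        R = X.T @ X
        off = R[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(10000) * np.sqrt(10000) * 0.05)
        assert np.all(np.abs(off) < 0.05)

    def test_seed_determinism(self, small_truth):
        a = sample_data(small_truth.sigma, 20, seed=9)
        b = sample_data(small_truth.sigma, 20, seed=9)
        assert np.array_equal(a, b)

    def test_rejects_single_sample(self, small_truth):
        with pytest.raises(ValueError):
            sample_data(small_truth.sigma, 1, seed=0)


class TestCorruptWeightMatrix:
    def test_full_accuracy_support_equals_truth(self, small_truth):
        w = corrupt_weight_matrix(small_truth, acc=1.0, seed=0)
        assert np.array_equal((w > 0).astype(int), small_truth.adjacency)

    def test_acc60_split_on_99_edges(self):
        from dwglasso import generate_scale_free_graph

        adj = generate_scale_free_graph(100, seed=1)
        truth = build_precision_matrix(adj)
        w = corrupt_weight_matrix(truth, acc=0.6, seed=4)
        sup = np.triu(w > 0, k=1)
        true_sup = np.triu(truth.adjacency > 0, k=1)
        n_correct = int((sup & true_sup).sum())
        n_wrong = int((sup & ~true_sup).sum())
        # round half-up: round(0.4 * 99) = 40 incorrect, 59 correct
        assert (n_wrong, n_correct) == (40, 59)

    @pytest.mark.parametrize("acc", [0.2, 0.4, 0.6, 0.8, 1.0])
    def test_support_size_preserved_and_ranges(self, small_truth, acc):
        w = corrupt_weight_matrix(small_truth, acc=acc, seed=7)
        assert np.triu(w > 0, k=1).sum() == small_truth.n_edges
        assert w.min() >= 0 and w.max() <= 1
        assert np.array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        # incorrect entries come from U(0, 0.5)
        wrong_mask = (w > 0) & (small_truth.adjacency == 0)
        if wrong_mask.any():
            assert w[wrong_mask].max() < 0.5

    def test_rejects_bad_acc(self, small_truth):
        for acc in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                corrupt_weight_matrix(small_truth, acc=acc, seed=0)


class TestTwoGroupData:
    def test_no_hubs_means_identical_truths(self):
        Xa, Xb, truth = generate_two_group_data(20, 15, 0, seed=3)
        assert np.array_equal(truth.truth_a.adjacency, truth.truth_b.adjacency)
        assert np.all(truth.true_dns() == 0)

    def test_reproducible(self):
        out1 = generate_two_group_data(20, 15, 2, seed=5)
        out2 = generate_two_group_data(20, 15, 2, seed=5)
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])
        assert out1[2].differential_nodes == out2[2].differential_nodes

    def test_hubs_have_larger_true_dns_than_background(self):
        _, _, truth = generate_two_group_data(100, 20, 3, seed=8)
        dns = truth.true_dns()
        hubs = truth.differential_nodes
        background = np.setdiff1d(np.arange(100), hubs)
        assert dns[hubs].min() > dns[background].max()
        assert dns[hubs].min() > 0

    def test_backbone_is_shared(self):
        _, _, truth = generate_two_group_data(60, 15, 2, seed=2)
        a = truth.truth_a.edges
        b = truth.truth_b.edges
        shared = len(a & b)
        assert shared / max(len(a), len(b)) >= 0.7

    def test_rejects_too_many_hubs(self):
        with pytest.raises(ValueError):
            generate_two_group_data(20, 15, 20, seed=0)
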