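"""Weighted graphical LASSO solver: optimality certificates, agreement
with independent minimizers, and the neighbor-selection baseline."""

import numpy as np
import pytest

from conftest import random_spd
from oracles import ista_glasso

from dwglasso import (
    PenaltySpec,
    glasso_fit,
    neighbor_selection_fit,
    network_from_estimate,
    wglasso_fit,
)
from dwglasso.solvers import kkt_residual, standardize_columns, support_edge_count, wglasso_objective


def random_weight(rng, p):
    w = rng.uniform(0, 1, size=(p, p))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0)
    return w


class TestWglassoOptimality:
    @pytest.mark.parametrize("p", [3, 5, 10])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_kkt_certificate_random_instances(self, p, weighted):
        rng = np.random.default_rng(100 * p + weighted)
        for _ in range(5):
            S = random_spd(rng, p)
            w = random_weight(rng, p) if weighted else None
            lam = rng.uniform(0.05, 0.4)
            est = wglasso_fit(S, PenaltySpec(lam=lam, w=w), tol=1e-6)
            assert est.converged
            assert kkt_residual(est, S) < 1e-5

    @pytest.mark.parametrize("p", [2, 3, 4])
    def test_objective_matches_proximal_gradient_oracle(self, p):
        rng = np.random.default_rng(p)
        S = random_spd(rng, p)
        w = random_weight(rng, p)
        pen = PenaltySpec(lam=0.2, w=w)
        est = wglasso_fit(S, pen, tol=1e-8)
        theta_ref = ista_glasso(S, pen.matrix(p))
        obj_ref = wglasso_objective(theta_ref, S, pen.matrix(p))
        assert est.objective_value == pytest.approx(obj_ref, abs=1e-4)
        assert np.allclose(est.theta, theta_ref, atol=1e-3)

    def test_all_ones_weights_recover_unpenalized_mle(self, rng):
        S = random_spd(rng, 6)
        w = np.ones((6, 6))
        np.fill_diagonal(w, 0)
        est = wglasso_fit(S, PenaltySpec(lam=0.3, w=w, penalize_diagonal=False), tol=1e-8)
        assert np.allclose(est.theta, np.linalg.inv(S), atol=1e-6)

    def test_full_shrinkage_gives_diagonal_estimate(self, rng):
        S = random_spd(rng, 8)
        lam = 1.01 * np.abs(S - np.diag(np.diag(S))).max()
        est = glasso_fit(S, lam)
        assert support_edge_count(est) == 0

    def test_matches_sklearn_scalar_penalty(self, rng):
        from sklearn.covariance import graphical_lasso

        S = random_spd(rng, 10)
        est = glasso_fit(S, 0.1, penalize_diagonal=False, tol=1e-7)
        _, prec = graphical_lasso(S, alpha=0.1, tol=1e-10, max_iter=500)
        assert np.allclose(est.theta, prec, atol=1e-4)

    def test_lam_zero_with_singular_s_raises(self, rng):
        X = rng.normal(size=(4, 8))
        S = X.T @ X / 4  # rank deficient
        with pytest.raises(np.linalg.LinAlgError):
            glasso_fit(S, 0.0)


class TestWglassoStructure:
    def test_glasso_equals_wglasso_with_zero_weights(self, rng):
        S = random_spd(rng, 7)
        a = glasso_fit(S, 0.15)
        b = wglasso_fit(S, PenaltySpec(lam=0.15, w=np.zeros((7, 7))))
        assert np.array_equal(a.theta, b.theta)

    def test_p2_soft_threshold_boundary(self):
        s = 0.5
        S = np.array([[1.0, s], [s, 1.0]])
        below = glasso_fit(S, 0.9 * s)
        above = glasso_fit(S, 1.1 * s)
        assert below.theta[0, 1] != 0
        assert above.theta[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_edge_count_monotone_in_lambda(self, rng):
        # Monotone over the operating range (lambda >= lam_max/10); in the
        # near-saturated dense tail single-edge dips can occur, so only
        # approximate monotonicity (within 3 edges of the running max) is
        # required there.
        from dwglasso import build_precision_matrix, generate_scale_free_graph, sample_data

        truth = build_precision_matrix(generate_scale_free_graph(20, seed=4))
        X = sample_data(truth.sigma, 40, seed=54)
        S = X.T @ X
        lam_max = np.abs(S - np.diag(np.diag(S))).max()
        grid = np.geomspace(lam_max, lam_max / 100, 50)
        counts = []
        est = None
        for lam in grid:
            est = glasso_fit(S, lam, warm_start=est)
            counts.append(support_edge_count(est))
        counts = np.array(counts)
        head = counts[grid >= lam_max / 10]
        assert np.all(np.diff(head) >= 0)
        assert np.all(np.maximum.accumulate(counts) - counts <= 3)

    def test_permutation_equivariance(self, rng):
        p = 8
        S = random_spd(rng, p)
        w = random_weight(rng, p)
        perm = rng.permutation(p)
        est = wglasso_fit(S, PenaltySpec(lam=0.2, w=w), tol=1e-7)
        est_p = wglasso_fit(
            S[np.ix_(perm, perm)], PenaltySpec(lam=0.2, w=w[np.ix_(perm, perm)]), tol=1e-7
        )
        assert np.allclose(est.theta[np.ix_(perm, perm)], est_p.theta, atol=1e-8)

    def test_higher_weight_favors_edge_retention(self, rng):
        # the same pair survives a penalty it would not survive without prior trust
        S = random_spd(rng, 5, jitter=0.3)
        i, j = 0, 1
        lam = 1.05 * abs(S[i, j])
        w = np.zeros((5, 5))
        w[i, j] = w[j, i] = 0.9
        plain = glasso_fit(S, lam)
        weighted = wglasso_fit(S, PenaltySpec(lam=lam, w=w))
        assert plain.theta[i, j] == pytest.approx(0.0, abs=1e-12)
        assert weighted.theta[i, j] != 0


class TestNetworkExtraction:
    def test_diagonal_estimate_gives_empty_network(self, rng):
        S = random_spd(rng, 6)
        lam = 1.05 * np.abs(S - np.diag(np.diag(S))).max()
        net = network_from_estimate(glasso_fit(S, lam))
        assert net.n_edges == 0
        assert all(v == 0 for v in net.degree.values())
        assert all(v == 0.0 for v in net.scaled_degree.values())

    def test_star_graph_scaled_degrees(self):
        from dwglasso.solvers import GeneNetwork

        nodes = ["hub", "a", "b", "c", "d"]
        net = GeneNetwork.from_edges(nodes, [("hub", x) for x in "abcd"])
        assert net.scaled_degree["hub"] == 1.0
        assert net.scaled_degree["a"] == 0.25

    def test_scaled_degree_consistent_with_reported_ratio(self):
        # a degree-2 gene in a max-degree-7 network has scaled degree 2/7
        from dwglasso.solvers import GeneNetwork

        nodes = [f"g{i}" for i in range(8)]
        edges = [("g0", f"g{i}") for i in range(1, 8)] + [("g1", "g2")]
        net = GeneNetwork.from_edges(nodes, edges)
        assert net.scaled_degree["g1"] == pytest.approx(2 / 7)
        assert round(net.scaled_degree["g1"], 3) == 0.286


class TestNeighborSelection:
    def test_large_lambda_empty_under_both_rules(self, rng):
        X = rng.normal(size=(30, 6))
        Xs = standardize_columns(X)
        lam = 1.05 * np.abs((Xs.T @ Xs) - np.eye(6)).max()
        for rule in ("or", "and"):
            assert neighbor_selection_fit(X, lam, rule).n_edges == 0

    def test_and_edges_subset_of_or_edges(self, rng):
        X = rng.normal(size=(40, 12))
        net_or = neighbor_selection_fit(X, 0.15, "or")
        net_and = neighbor_selection_fit(X, 0.15, "and")
        assert net_and.edges <= net_or.edges

    def test_recovers_path_graph_structure(self):
        # p=3 chain: tune to 2 edges, expect the true path most of the time
        from dwglasso import build_precision_matrix, sample_data
        from dwglasso.model_selection import tune_ns_to_sparsity

        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1
        truth = build_precision_matrix(adj)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            X = sample_data(truth.sigma, 50, seed=seed)
            _, net, _ = tune_ns_to_sparsity(X, 2, rule="or")
            if net.edges == {("g1", "g2"), ("g2", "g3")}:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_constant_column_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        X[:, 2] = 1.0
        with pytest.raises(ValueError):
            neighbor_selection_fit(X, 0.1, "or")
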