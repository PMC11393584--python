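import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from psynet._glasso import glasso_fit, glasso_path, penalized_objective
from psynet.errors import EstimationError
from psynet.ggm import (
    CorrelationInput,
    correlation_matrix,
    ebic,
    estimate_network,
    lambda_grid,
    network_summary,
    precision_to_pcor,
)
from psynet.simulate import make_true_network, pcor_to_covariance


def brute_force_glasso(S, lam, eps=1e-8):
    """Direct numeric maximization of the penalized log-likelihood with a
    smoothed L1 term; independent of the coordinate-descent path."""
    p = S.shape[0]
    iu, ju = np.triu_indices(p, 1)

    def unpack(x):
        T = np.zeros((p, p))
        T[np.diag_indices(p)] = x[:p]
        T[iu, ju] = T[ju, iu] = x[p:]
        return T

    def neg_obj(x):
        T = unpack(x)
        sign, logdet = np.linalg.slogdet(T)
        if sign <= 0:
            return 1e12
        pen = 2.0 * np.sum(np.sqrt(x[p:] ** 2 + eps**2))
        return -(logdet - np.trace(S @ T) - lam * pen)

    x0 = np.concatenate([np.ones(p), np.zeros(len(iu))])
    res = minimize(neg_obj, x0, method="Powell",
                   options={"maxiter": 200_000, "xtol": 1e-10, "ftol": 1e-12})
    res = minimize(neg_obj, res.x, method="Powell",
                   options={"maxiter": 200_000, "xtol": 1e-12, "ftol": 1e-14})
    return unpack(res.x)


def _corr_from_data(p, n, seed, shared=0.7):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X[:, : max(2, p // 2)] += shared * rng.normal(size=(n, 1))
    return np.corrcoef(X, rowvar=False)


class TestGlassoKernel:
    def test_identity_input_gives_identity_precision(self):
        for lam in (0.0, 0.1, 0.5):
            Th = glasso_fit(np.eye(5), lam)
            assert np.allclose(Th, np.eye(5), atol=1e-10)

    def test_penalty_above_screening_bound_empties_graph(self):
        S = _corr_from_data(6, 500, 0)
        lam_max = np.abs(S - np.eye(6)).max()
        Th = glasso_fit(S, lam_max * 1.0001)
        assert np.count_nonzero(np.triu(Th, 1)) == 0

    @pytest.mark.parametrize("p, lam", [(2, 0.05), (3, 0.1), (4, 0.15)])
    def test_matches_brute_force_optimum(self, p, lam):
        S = _corr_from_data(p, 400, seed=p)
        ours = glasso_fit(S, lam)
        ref = brute_force_glasso(S, lam)
        assert np.abs(ours - ref).max() < 1e-4

    @pytest.mark.parametrize("lam", [0.02, 0.08, 0.2])
    def test_matches_sklearn_precision(self, lam):
        """Independent solver cross-check at p = 10."""
        from sklearn.covariance import graphical_lasso

        S = _corr_from_data(10, 2000, 1)
        ours = glasso_fit(S, lam)
        _, ref = graphical_lasso(S, alpha=lam, tol=1e-10, enet_tol=1e-14,
                                 max_iter=10_000)
        assert np.abs(ours - ref).max() < 1e-4

    def test_lambda_to_zero_recovers_inverse_correlation(self):
        rng = np.random.default_rng(5)
        S = np.corrcoef(rng.normal(size=(5000, 8)), rowvar=False)
        Th = glasso_fit(S, 1e-6)
        ref = precision_to_pcor(np.linalg.inv(S))
        assert np.abs(precision_to_pcor(Th) - ref).max() < 1e-3

    def test_monotone_sparsity_along_path(self):
        S = _corr_from_data(10, 400, 2)
        grid = lambda_grid(S, 40)
        counts = [int(np.count_nonzero(np.triu(T, 1))) for T in glasso_path(S, grid)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))  # lam descends


class TestLambdaGrid:
    def test_endpoints_and_length(self):
        S = np.eye(3)
        S[0, 1] = S[1, 0] = 0.5
        grid = lambda_grid(S, n_lambda=100, min_ratio=0.01)
        assert len(grid) == 100
        assert grid[0] == pytest.approx(0.5)
        assert grid[-1] == pytest.approx(0.005)

    def test_two_point_grid(self):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = 0.4
        grid = lambda_grid(S, n_lambda=2, min_ratio=0.1)
        assert grid == pytest.approx([0.4, 0.04])

    def test_strictly_decreasing(self):
        S = _corr_from_data(6, 300, 3)
        grid = lambda_grid(S, 30)
        assert (np.diff(grid) < 0).all()

    def test_all_zero_offdiagonals_warn(self):
        with pytest.warns(UserWarning):
            grid = lambda_grid(np.eye(4))
        assert grid.tolist() == [0.0]


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        S = _corr_from_data(5, 300, 4)
        Th = glasso_fit(S, 0.05)
        E = int(np.count_nonzero(np.triu(Th, 1)))
        n = 300
        sign, logdet = np.linalg.slogdet(Th)
        L = 0.5 * n * (logdet - np.trace(S @ Th))
        assert ebic(Th, S, n, gamma=0.0) == pytest.approx(-2 * L + E * np.log(n))

    def test_hand_evaluated_two_node_instance(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        Th = np.array([[1.2, -0.4], [-0.4, 1.2]])
        n, gamma = 50, 0.5
        logdet = np.log(1.2 * 1.2 - 0.16)
        L = 0.5 * n * (logdet - (1.2 + 1.2 + 2 * 0.3 * -0.4))
        expected = -2 * L + 1 * np.log(50) + 4 * 1 * gamma * np.log(2)
        assert ebic(Th, S, n, gamma) == pytest.approx(expected, abs=1e-10)

    def test_diagonal_model_has_zero_penalty_term(self):
        # Theta = I on S = I: L = (n/2)(0 - p), E = 0, so EBIC = -2L = n p
        assert ebic(np.eye(4), np.eye(4), 100) == pytest.approx(400.0, abs=1e-10)


class TestCorrelationMatrix:
    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(6)
        corr = correlation_matrix(rng.normal(size=(100_000, 5)))
        off = corr.matrix - np.eye(5)
        assert np.abs(off).max() < 0.02

    def test_symmetric_unit_diagonal(self, likert600):
        corr = correlation_matrix(likert600)
        assert np.allclose(corr.matrix, corr.matrix.T)
        assert np.allclose(np.diag(corr.matrix), 1.0)

    def test_constant_item_raises_naming_it(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 1.0})
        with pytest.raises(EstimationError, match="b"):
            correlation_matrix(X)

    def test_spearman_option(self, likert600):
        corr = correlation_matrix(likert600, method="spearman")
        assert corr.method == "spearman"
        assert np.abs(corr.matrix).max() <= 1.0


class TestEstimateNetwork:
    def test_empty_truth_yields_almost_no_edges(self):
        rng = np.random.default_rng(11)
        X = rng.multivariate_normal(np.zeros(10), np.eye(10), 5000)
        net = estimate_network(X)
        assert net.edge_count() <= 1

    def test_planted_ten_node_pattern_recovered(self):
        net0 = make_true_network(p=10, density=0.3, weight_range=(0.15, 0.35), seed=8)
        cov = pcor_to_covariance(net0)
        rng = np.random.default_rng(8)
        X = rng.multivariate_normal(np.zeros(10), cov, 5000)
        est = estimate_network(X)
        iu = np.triu_indices(10, 1)
        truth = (net0.pcor != 0)[iu]
        found = (est.weights != 0)[iu]
        sensitivity = (truth & found).sum() / truth.sum()
        assert sensitivity >= 0.9

    def test_weights_are_partial_correlations_of_precision(self, likert600):
        net = estimate_network(likert600, n_lambda=30)
        assert np.allclose(net.weights, precision_to_pcor(net.precision), atol=1e-12)
        assert np.abs(net.weights).max() < 1.0
        assert ((net.weights != 0) == (np.abs(net.precision
                - np.diag(np.diag(net.precision))) > 0)).all()

    def test_deterministic(self, likert600):
        a = estimate_network(likert600, n_lambda=30)
        b = estimate_network(likert600, n_lambda=30)
        assert np.array_equal(a.weights, b.weights)
        assert a.lambda_ == b.lambda_

    def test_minimum_sample_size_enforced(self):
        X = np.random.default_rng(0).normal(size=(8, 5))
        with pytest.raises(EstimationError):
            estimate_network(X)


class TestNetworkSummary:
    def test_ten_nodes_have_45_possible_edges(self, likert600):
        net = estimate_network(likert600, n_lambda=30)
        s = network_summary(net)
        assert s["possible_edges"] == 45

    def test_percentage_of_39_in_45(self):
        # synthetic network object with exactly 39 edges
        W = np.zeros((10, 10))
        iu, ju = np.triu_indices(10, 1)
        for k in range(39):
            W[iu[k], ju[k]] = W[ju[k], iu[k]] = 0.1
        from psynet.ggm import PartialCorrelationNetwork

        net = PartialCorrelationNetwork([f"S{i}" for i in range(10)], W,
                                        np.eye(10), 0.1, 0.5, 0.0, 100)
        s = network_summary(net)
        assert s["nonzero_edges"] == 39
        assert s["pct_nonzero"] == pytest.approx(86.67, abs=0.01)

    def test_empty_network_has_no_mean_weight(self):
        from psynet.ggm import PartialCorrelationNetwork

        net = PartialCorrelationNetwork(["a", "b"], np.zeros((2, 2)),
                                        np.eye(2), 0.1, 0.5, 0.0, 100)
        assert network_summary(net)["mean_abs_weight"] is None
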