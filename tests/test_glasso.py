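import numpy as np
import pytest

from mirlasso.glasso import (
    CovarianceInput, GlassoError, GraphicalLassoModel, empirical_covariance,
    graphical_lasso, penalized_loglik, regularization_path,
)
from mirlasso.glasso_reference import optimality_residual, reference_graphical_lasso
from mirlasso.io import MIRNA, MRNA

from conftest import make_expr, random_correlation


def _cov(S, n=100):
    m = S.shape[0]
    return CovarianceInput(np.asarray(S, float), [f"f{i}" for i in range(m)],
                           [MRNA] * m, n=n)


class TestEmpiricalCovariance:
    def test_hand_computed_one_over_n_covariance(self):
        Z = make_expr([[1, 2, 0], [4, 0, 1], [2, 3, 5], [7, 1, 2]])
        cov = empirical_covariance(Z)
        expected = [[5.25, -1.5, 0.0], [-1.5, 1.25, 1.25], [0.0, 1.25, 3.5]]
        np.testing.assert_allclose(cov.S, expected, atol=1e-12)
        assert cov.n == 4

    def test_collinear_columns_have_unit_correlation(self):
        Z = make_expr([[1, 2], [2, 4], [3, 6]])
        cov = empirical_covariance(Z, scale="correlation")
        assert cov.S[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero_offdiagonal(self):
        rng = np.random.default_rng(0)
        Z = make_expr(rng.standard_normal((4000, 3)) + 10)
        cov = empirical_covariance(Z, scale="correlation")
        off = cov.S[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.06

    def test_constant_columns_dropped_and_reported(self):
        Z = make_expr([[1, 5, 2], [2, 5, 1], [3, 5, 4]])
        cov = empirical_covariance(Z)
        assert cov.dropped_features == ["f1"]
        assert cov.feature_ids == ["f0", "f2"]

    def test_all_constant_is_error(self):
        Z = make_expr([[5, 5], [5, 5]])
        with pytest.raises(ValueError, match="constant"):
            empirical_covariance(Z)

    def test_single_sample_is_error(self):
        Z = make_expr([[1.0, 2.0]])
        with pytest.raises(ValueError, match="2 samples"):
            empirical_covariance(Z)

    def test_group_centering_removes_mean_shift(self):
        rng = np.random.default_rng(5)
        n = 200
        X = rng.standard_normal((2 * n, 2))
        X[:n] += 5.0  # group shift correlates the two features globally
        Z = make_expr(X + 10)
        ga = (Z.sample_ids[:n], Z.sample_ids[n:])
        cov_global = empirical_covariance(Z, scale="correlation")
        cov_group = empirical_covariance(Z, scale="correlation", groups=ga)
        assert cov_global.S[0, 1] > 0.7
        assert abs(cov_group.S[0, 1]) < 0.15


class TestGraphicalLassoAnalytic:
    def test_diagonal_covariance_closed_form(self):
        s = np.array([1.0, 2.0, 3.0, 0.5])
        res = graphical_lasso(_cov(np.diag(s)), rho=0.7)
        np.testing.assert_allclose(res.theta, np.diag(1.0 / (s + 0.7)), atol=1e-10)
        assert res.converged and res.n_edges() == 0

    def test_two_by_two_soft_threshold_closed_form(self):
        S = np.array([[1.0, 0.8], [0.8, 1.0]])
        res = GraphicalLassoModel(_cov(S), rho=0.3).fit(tol=1e-8, inner_tol=1e-10)
        W = np.array([[1.3, 0.5], [0.5, 1.3]])
        np.testing.assert_allclose(res.W, W, atol=1e-8)
        np.testing.assert_allclose(res.theta, np.linalg.inv(W), atol=1e-8)

    def test_full_shrinkage_above_max_offdiagonal(self):
        rng = np.random.default_rng(2)
        S = random_correlation(rng, 5)
        rho = np.abs(S[~np.eye(5, dtype=bool)]).max()
        res = graphical_lasso(_cov(S), rho=rho * 1.0000001)
        assert res.n_edges() == 0
        np.testing.assert_allclose(
            res.theta, np.diag(1.0 / (np.diag(S) + res.rho)), atol=1e-8
        )

    def test_rho_zero_recovers_plain_inverse(self):
        rng = np.random.default_rng(3)
        S = random_correlation(rng, 4)
        res = GraphicalLassoModel(_cov(S), rho=0.0).fit(tol=1e-9, inner_tol=1e-12,
                                                        max_iter=500)
        np.testing.assert_allclose(res.theta, np.linalg.inv(S), atol=1e-6)


class TestGraphicalLassoProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_proximal_gradient_reference(self, seed):
        rng = np.random.default_rng(seed)
        m = 3 + seed % 4
        S = random_correlation(rng, m)
        res = GraphicalLassoModel(_cov(S), rho=0.2).fit(tol=1e-7, inner_tol=1e-9,
                                                        max_iter=200)
        ref = reference_graphical_lasso(S, 0.2, opt_tol=1e-8)
        assert np.abs(res.theta - ref).max() < 1e-4

    def test_matches_sklearn_unpenalized_diagonal_convention(self):
        sklearn_cov = pytest.importorskip("sklearn.covariance")
        rng = np.random.default_rng(10)
        S = random_correlation(rng, 5)
        _, theta_sk = sklearn_cov.graphical_lasso(S, alpha=0.15, tol=1e-10)
        res = GraphicalLassoModel(_cov(S), rho=0.15, penalize_diagonal=False).fit(
            tol=1e-8, inner_tol=1e-10, max_iter=500
        )
        assert np.abs(res.theta - theta_sk).max() < 5e-3

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_beats_diagonal_feasible_point(self, seed):
        rng = np.random.default_rng(100 + seed)
        S = random_correlation(rng, 6)
        rho = 0.15
        res = graphical_lasso(_cov(S), rho=rho)
        diag_point = np.diag(1.0 / (np.diag(S) + rho))
        assert res.objective >= penalized_loglik(diag_point, S, rho) - 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_kkt_certificate_and_dual_identity(self, seed):
        rng = np.random.default_rng(200 + seed)
        S = random_correlation(rng, 7)
        res = graphical_lasso(_cov(S), rho=0.2, tol=1e-6)
        assert res.converged
        assert res.kkt_bound_violation <= 1e-6 + 1e-12
        assert res.kkt_active_residual <= 1e-4
        assert np.abs(res.W @ res.theta - np.eye(7)).max() < 1e-4
        # stationarity of the recovered primal point
        assert optimality_residual(res.theta, S, 0.2) < 1e-3

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        S = random_correlation(rng, 6)
        perm = rng.permutation(6)
        res = graphical_lasso(_cov(S), rho=0.1, tol=1e-7)
        res_p = graphical_lasso(_cov(S[np.ix_(perm, perm)]), rho=0.1, tol=1e-7)
        np.testing.assert_allclose(res_p.theta, res.theta[np.ix_(perm, perm)],
                                   atol=1e-5)

    def test_edge_set_invariant_to_feature_rescaling_on_correlation_scale(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((300, 5)) @ rng.standard_normal((5, 5))
        Z = make_expr(X - X.min() + 1)
        scales = np.array([1.0, 10.0, 0.3, 5.0, 2.0])
        Zs = make_expr((X - X.min() + 1) * scales)
        r1 = GraphicalLassoModel.from_expression(Z, rho=0.2, transform="none").fit()
        r2 = GraphicalLassoModel.from_expression(Zs, rho=0.2, transform="none").fit()
        assert {frozenset(e[:2]) for e in r1.edges()} == {
            frozenset(e[:2]) for e in r2.edges()
        }

    def test_positive_definite_theta_and_symmetric_support(self):
        rng = np.random.default_rng(9)
        S = random_correlation(rng, 8)
        res = graphical_lasso(_cov(S), rho=0.1)
        assert np.linalg.eigvalsh(res.theta)[0] > 0
        np.testing.assert_array_equal(
            np.abs(res.theta) > 1e-8, (np.abs(res.theta) > 1e-8).T
        )

    def test_negative_rho_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            GraphicalLassoModel(_cov(np.eye(2)), rho=-1.0)

    def test_rho_zero_singular_covariance_rejected(self):
        S = np.ones((3, 3))  # rank one, strictly positive diagonal
        with pytest.raises(GlassoError, match="nonsingular"):
            GraphicalLassoModel(_cov(S), rho=0.0).fit()


class TestRegularizationPath:
    def test_large_rho_gives_single_diagonal_estimate(self):
        rng = np.random.default_rng(12)
        S = random_correlation(rng, 5)
        (res,) = regularization_path(_cov(S), [2.0])
        assert res.n_edges() == 0

    def test_endpoint_edge_counts_ordered(self):
        rng = np.random.default_rng(13)
        S = random_correlation(rng, 8)
        path = regularization_path(_cov(S), [0.4, 0.05])
        assert path[0].rho > path[-1].rho
        assert path[0].n_edges() <= path[-1].n_edges()

    @pytest.mark.parametrize("seed", range(3))
    def test_warm_start_matches_cold_start(self, seed):
        rng = np.random.default_rng(20 + seed)
        S = random_correlation(rng, 6)
        rhos = [0.3, 0.2, 0.1]
        tol = 1e-7
        warm = regularization_path(_cov(S), rhos, tol=tol, max_iter=300)
        for res in warm:
            cold = GraphicalLassoModel(_cov(S), rho=res.rho).fit(tol=tol, max_iter=300)
            assert np.abs(res.theta - cold.theta).max() < 10 * 1e-5

    def test_rhos_sorted_internally(self):
        rng = np.random.default_rng(14)
        S = random_correlation(rng, 4)
        up = regularization_path(_cov(S), [0.1, 0.2, 0.3])
        down = regularization_path(_cov(S), [0.3, 0.2, 0.1])
        for a, b in zip(up, down):
            assert a.rho == b.rho
            np.testing.assert_allclose(a.theta, b.theta, atol=1e-12)

    def test_nonpositive_rho_in_path_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            regularization_path(_cov(np.eye(2)), [0.5, 0.0])


def test_summary_mentions_key_quantities():
    rng = np.random.default_rng(15)
    S = random_correlation(rng, 4)
    cov = CovarianceInput(S, ["m1", "m2", "g1", "g2"],
                          [MIRNA, MIRNA, MRNA, MRNA], n=100)
    res = GraphicalLassoModel(cov, rho=0.1).fit()
    text = res.summary()
    assert "Penalty rho" in text and "miRNA-mRNA" in text and "Converged" in text
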