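"""Graphical lasso estimator: closed-form oracles, KKT conditions, CV."""

import numpy as np
import pytest

from covnet.precision import (
    empirical_covariance,
    fit_graphical_lasso,
    fit_group_network,
    kkt_residual,
    partial_correlations,
    penalty_upper_bound,
    select_penalty_cv,
)


class TestEmpiricalCovariance:
    def test_identical_columns_give_unit_offdiagonal(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        S = empirical_covariance(np.column_stack([x, x]))
        assert S[0, 1] == pytest.approx(S[0, 0])
        C = S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
        assert C[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_identity(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100_000, 19))
        S = empirical_covariance(X)
        assert np.abs(S - np.eye(19)).max() < 0.05

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            empirical_covariance(np.ones((1, 3)))

    def test_nonfinite_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            empirical_covariance(X)


class TestGraphicalLasso:
    def test_zero_penalty_equals_closed_form_inverse_2x2(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        model = fit_graphical_lasso(S, penalty=0.0)
        expected = np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]])
        np.testing.assert_allclose(model.precision, expected, atol=1e-12)

    def test_zero_penalty_equals_inverse_19x19(self, base_covariance):
        rng = np.random.default_rng(3)
        X = rng.multivariate_normal(np.zeros(19), base_covariance, size=500)
        S = empirical_covariance(X)
        model = fit_graphical_lasso(S, penalty=0.0)
        np.testing.assert_allclose(model.precision, np.linalg.inv(S), atol=1e-6)

    def test_large_penalty_gives_diagonal_model(self, base_covariance):
        rng = np.random.default_rng(4)
        X = rng.multivariate_normal(np.zeros(19), base_covariance, size=200)
        S = empirical_covariance(X)
        lam = penalty_upper_bound(S) * 1.01
        model = fit_graphical_lasso(S, lam)
        off = model.precision[~np.eye(19, dtype=bool)]
        assert np.all(off == 0)
        np.testing.assert_allclose(np.diag(model.precision), 1 / np.diag(S), rtol=1e-3)
        assert kkt_residual(S, model.precision, lam) <= 1e-4

    def test_kkt_residual_small_at_solution(self, base_covariance):
        rng = np.random.default_rng(5)
        X = rng.multivariate_normal(np.zeros(19), base_covariance, size=2000)
        X = (X - X.mean(0)) / X.std(0)
        S = empirical_covariance(X)
        for lam in (0.02, 0.05, 0.1):
            model = fit_graphical_lasso(S, lam, tol=1e-7, enet_tol=1e-8, max_iter=1000)
            assert kkt_residual(S, model.precision, lam) <= 1e-4

    def test_support_recovery_on_sparse_truth(self, base_precision, base_covariance):
        rng = np.random.default_rng(6)
        X = rng.multivariate_normal(np.zeros(19), base_covariance, size=10_000)
        X = (X - X.mean(0)) / X.std(0)
        model = fit_graphical_lasso(empirical_covariance(X), penalty=0.01)
        off = np.triu_indices(19, k=1)
        true_edges = set(map(tuple, np.argwhere(np.abs(base_precision) > 1e-10)))
        est = model.precision
        inter = union = 0
        for i, j in zip(*off):
            t = (i, j) in true_edges
            e = abs(est[i, j]) > 1e-10
            inter += t and e
            union += t or e
        assert inter / union >= 0.8

    def test_monotone_sparsity_in_penalty(self, base_covariance):
        rng = np.random.default_rng(7)
        X = rng.multivariate_normal(np.zeros(19), base_covariance, size=100)
        X = (X - X.mean(0)) / X.std(0)
        S = empirical_covariance(X)
        nnz = []
        for lam in (0.02, 0.05, 0.1, 0.2, 0.4):
            m = fit_graphical_lasso(S, lam)
            nnz.append(int(np.count_nonzero(m.precision) - 19))
        assert nnz == sorted(nnz, reverse=True)

    def test_permutation_equivariance(self, base_covariance):
        rng = np.random.default_rng(8)
        X = rng.multivariate_normal(np.zeros(19), base_covariance, size=150)
        X = (X - X.mean(0)) / X.std(0)
        perm = rng.permutation(19)
        m1 = fit_graphical_lasso(
            empirical_covariance(X), 0.05, tol=1e-7, enet_tol=1e-8, max_iter=1000
        )
        m2 = fit_graphical_lasso(
            empirical_covariance(X[:, perm]), 0.05, tol=1e-7, enet_tol=1e-8, max_iter=1000
        )
        np.testing.assert_allclose(
            m2.precision, m1.precision[np.ix_(perm, perm)], atol=1e-5
        )
        np.testing.assert_allclose(m2.pcorr, m1.pcorr[np.ix_(perm, perm)], atol=1e-5)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fit_graphical_lasso(np.eye(2), -0.1)


class TestPartialCorrelations:
    def test_identity_precision_gives_identity(self):
        np.testing.assert_array_equal(partial_correlations(np.eye(4)), np.eye(4))

    def test_two_by_two_closed_form(self):
        theta = np.array([[2.0, 1.0], [1.0, 2.0]])
        P = partial_correlations(theta)
        assert P[0, 1] == pytest.approx(-0.5)
        assert P[0, 0] == P[1, 1] == 1.0

    def test_chain_zero_partial_but_nonzero_marginal(self):
        # 1 - 2 - 3 chain: theta_13 = 0, but marginal corr(1,3) != 0
        theta = np.array([[1.5, -0.6, 0.0], [-0.6, 1.8, -0.6], [0.0, -0.6, 1.5]])
        P = partial_correlations(theta)
        assert P[0, 2] == 0.0
        cov = np.linalg.inv(theta)
        corr13 = cov[0, 2] / np.sqrt(cov[0, 0] * cov[2, 2])
        assert abs(corr13) > 0.05
        # closed form for the nonzero entries
        assert P[0, 1] == pytest.approx(0.6 / np.sqrt(1.5 * 1.8))

    def test_bounds_and_symmetry(self, base_precision):
        P = partial_correlations(base_precision)
        assert np.all(np.abs(P) <= 1.0)
        np.testing.assert_allclose(P, P.T)
        np.testing.assert_allclose(np.diag(P), 1.0)

    def test_nonpositive_diagonal_rejected(self):
        theta = np.array([[1.0, 0.0], [0.0, -1.0]])
        with pytest.raises(ValueError, match="diagonal"):
            partial_correlations(theta)


class TestPenaltySelection:
    def test_deterministic_given_seed(self, base_covariance):
        rng = np.random.default_rng(9)
        X = rng.multivariate_normal(np.zeros(19), base_covariance, size=60)
        lam1, grid1 = select_penalty_cv(X, seed=11)
        lam2, grid2 = select_penalty_cv(X, seed=11)
        assert lam1 == lam2
        assert grid1 == grid2

    def test_dense_truth_prefers_weak_penalty(self):
        rng = np.random.default_rng(10)
        # dense strong-precision model: equicorrelated covariance
        cov = 0.5 * np.eye(6) + 0.5
        X = rng.multivariate_normal(np.zeros(6), cov, size=400)
        X = (X - X.mean(0)) / X.std(0)
        lam, _ = select_penalty_cv(X, seed=0)
        lam_max = penalty_upper_bound(empirical_covariance(X))
        assert lam < 0.1 * lam_max

    def test_independent_columns_prefer_strong_penalty(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 10))
        lam, _ = select_penalty_cv(X, seed=0)
        lam_max = penalty_upper_bound(empirical_covariance(X))
        assert lam > 0.3 * lam_max

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            select_penalty_cv(np.random.default_rng(0).standard_normal((8, 4)))


def test_fit_group_network_records_cv_grid(base_covariance):
    rng = np.random.default_rng(13)
    X = rng.multivariate_normal(np.zeros(19), base_covariance, size=64)
    model = fit_group_network(X, penalty=None, seed=3)
    assert model.cv_grid is not None
    assert model.penalty in [lam for lam, _ in model.cv_grid]
    # the invariants of the fitted model
    eig = np.linalg.eigvalsh(model.precision)
    assert eig.min() > 0
    assert np.all(np.abs(model.pcorr) <= 1 + 1e-12)
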