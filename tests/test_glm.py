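"""IRLS fitting, hat matrix, residuals, and the condition index."""

import numpy as np
import pytest
from scipy.optimize import minimize

from poisliu import (
    ModelData,
    PoissonRegression,
    RankDeficientDesignError,
    condition_index,
    hat_matrix,
    irls_fit,
    leverages,
    residuals,
)
from poisliu.glm import pearson_ratio, poisson_deviance, poisson_loglik

from conftest import make_problem


class TestIRLS:
    def test_intercept_only_closed_form(self):
        """With no regressors the MLE of the mean is the sample mean."""
        y = np.array([3.0, 3.0, 3.0, 3.0])
        X = np.empty((4, 0))
        model = PoissonRegression().fit(X, y)
        assert model.converged_
        np.testing.assert_allclose(model.beta_, [np.log(3.0)], rtol=1e-10)
        np.testing.assert_allclose(model.mu_, 3.0, rtol=1e-10)

    def test_matches_direct_likelihood_maximization(self):
        """IRLS solution agrees with a general-purpose optimizer."""
        X, y = make_problem(42, n=30, p=2)
        model = PoissonRegression(tol=1e-10).fit(X, y)
        A = np.column_stack([np.ones(len(y)), X])

        def nll(beta):
            return -poisson_loglik(y, np.exp(A @ beta))

        res = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(model.beta_, res.x, atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_statsmodels(self, seed):
        """Cross-check against an independent GLM fitter on random data."""
        sm = pytest.importorskip("statsmodels.api")
        X, y = make_problem(seed)
        model = PoissonRegression(tol=1e-10).fit(X, y)
        A = np.column_stack([np.ones(len(y)), X])
        ref = sm.GLM(y, A, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(model.beta_, ref.params, atol=1e-6)
        np.testing.assert_allclose(model.deviance_, ref.deviance, rtol=1e-6)

    def test_fixed_point_self_consistency(self, small_fit):
        """At convergence beta solves the weighted LS equations in W(beta), z(beta)."""
        model, X, y = small_fit
        A = np.column_stack([np.ones(len(y)), X])
        mu = np.exp(A @ model.beta_)
        z = A @ model.beta_ + (y - mu) / mu
        beta_next = np.linalg.solve(A.T @ (mu[:, None] * A), A.T @ (mu * z))
        np.testing.assert_allclose(beta_next, model.beta_, atol=1e-7)

    def test_weights_equal_fitted_means(self, small_fit):
        model, X, y = small_fit
        np.testing.assert_array_equal(model.weights_, model.mu_)

    def test_nonconvergence_is_flagged_not_raised(self):
        X, y = make_problem(3)
        model = PoissonRegression(max_iter=1, tol=1e-14).fit(X, y)
        assert not model.converged_
        assert np.all(np.isfinite(model.beta_))

    def test_duplicate_column_raises_rank_error(self):
        X, y = make_problem(5)
        X2 = np.column_stack([X, X[:, 0]])
        with pytest.raises(RankDeficientDesignError):
            PoissonRegression().fit(X2, y)

    def test_modeldata_validation(self):
        with pytest.raises(ValueError, match="nonnegative integer"):
            ModelData(y=[1, -1, 2, 0, 1], X=np.ones((5, 1)))
        with pytest.raises(ValueError, match="n > p"):
            ModelData(y=[1, 2], X=np.random.default_rng(0).normal(size=(2, 2)))
        with pytest.raises(ValueError, match="non-finite"):
            ModelData(y=[1, 2, 3, 4], X=[[np.nan], [1.0], [2.0], [0.5]])

    def test_irls_fit_wrapper(self, football):
        model = irls_fit(football)
        assert model.converged_
        assert len(model.beta_) == football.p + 1


class TestHatMatrix:
    def test_projection_properties(self, small_fit):
        """Trace equals the coefficient count; H is symmetric idempotent."""
        model, X, y = small_fit
        H = hat_matrix(model, X)
        assert H.shape == (len(y), len(y))
        np.testing.assert_allclose(np.trace(H), X.shape[1] + 1, rtol=1e-10)
        np.testing.assert_allclose(H, H.T, atol=1e-10)
        assert np.max(np.abs(H @ H - H)) < 1e-8
        h = leverages(model, X)
        np.testing.assert_allclose(h, np.diag(H), atol=1e-12)
        assert np.all(h >= 0) and np.all(h <= 1)

    def test_elementwise_against_dense_formula(self):
        """Brute-force W^{1/2}X(X'WX)^{-1}X'W^{1/2} on a 5-point toy."""
        X, y = make_problem(11, n=5, p=1)
        model = PoissonRegression().fit(X, y)
        A = np.column_stack([np.ones(5), X])
        W = np.diag(model.weights_)
        Wh = np.sqrt(W)
        H_ref = Wh @ A @ np.linalg.inv(A.T @ W @ A) @ A.T @ Wh
        np.testing.assert_allclose(hat_matrix(model, X), H_ref, atol=1e-10)


class TestResiduals:
    def test_zero_residual_everywhere_on_saturated_fit(self):
        """A design rich enough to interpolate gives chi = d = 0."""
        y = np.array([2.0, 2.0, 7.0, 7.0])
        X = np.array([[0.0], [0.0], [1.0], [1.0]])  # two-group design: fit hits group means
        model = PoissonRegression(fit_intercept=True, tol=1e-12, max_iter=200).fit(X, y)
        chi, chis, dev = residuals(model, X, y)
        np.testing.assert_allclose(chi, 0.0, atol=1e-6)
        np.testing.assert_allclose(dev, 0.0, atol=1e-6)

    def test_deviance_residuals_sum_to_deviance(self, small_fit):
        model, X, y = small_fit
        _, _, dev = residuals(model, X, y)
        np.testing.assert_allclose(np.sum(dev**2), model.deviance_, rtol=1e-8)

    def test_deviance_equals_likelihood_ratio(self):
        """Deviance equals twice the saturated-minus-fitted log-likelihood."""
        X, y = make_problem(13, n=12, p=1)
        model = PoissonRegression().fit(X, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_sat = float(np.sum(np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0)) - y, 0.0)))
        ll_fit = float(np.sum(y * np.log(model.mu_) - model.mu_))
        np.testing.assert_allclose(model.deviance_, 2 * (ll_sat - ll_fit), rtol=1e-8)
        assert poisson_deviance(y, model.mu_) == model.deviance_

    def test_zero_count_convention(self):
        X, y = make_problem(17, n=15, p=1, beta_scale=0.1)
        y[0] = 0.0
        model = PoissonRegression().fit(X, y)
        chi, _, dev = residuals(model, X, y)
        assert np.isfinite(chi).all() and np.isfinite(dev).all()
        assert dev[0] < 0  # y=0 always below a positive fitted mean

    def test_sign_matches_raw_residual(self, small_fit):
        model, X, y = small_fit
        chi, _, dev = residuals(model, X, y)
        mu = model.predict(X)
        np.testing.assert_array_equal(np.sign(dev), np.sign(y - mu))
        np.testing.assert_allclose(
            pearson_ratio(model, X, y), (y - mu) / mu, atol=1e-12
        )

    def test_permutation_equivariance(self, small_fit):
        """Reordering observations permutes residuals and leverages identically."""
        model, X, y = small_fit
        perm = np.random.default_rng(0).permutation(len(y))
        model_p = PoissonRegression().fit(X[perm], y[perm])
        chi, chis, dev = residuals(model, X, y)
        chi_p, chis_p, dev_p = residuals(model_p, X[perm], y[perm])
        np.testing.assert_allclose(chi_p, chi[perm], atol=1e-8)
        np.testing.assert_allclose(dev_p, dev[perm], atol=1e-8)
        np.testing.assert_allclose(
            leverages(model_p, X[perm]), leverages(model, X)[perm], atol=1e-8
        )


class TestConditionIndex:
    def test_orthonormal_columns_give_one(self):
        rng = np.random.default_rng(2)
        # exactly uncorrelated, equal-variance columns: all eigenvalues equal
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        np.testing.assert_allclose(condition_index(X, "correlation"), 1.0, atol=1e-12)

    def test_duplicated_column_raises(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20)
        with pytest.raises(RankDeficientDesignError):
            condition_index(np.column_stack([x, x]), "correlation")

    def test_scale_invariance_of_correlation_form(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 3))
        ci1 = condition_index(X, "correlation")
        ci2 = condition_index(X * np.array([1.0, 100.0, 0.01]), "correlation")
        np.testing.assert_allclose(ci1, ci2, rtol=1e-10)

    def test_weighted_convention_needs_weights(self):
        X = np.random.default_rng(5).standard_normal((10, 2))
        with pytest.raises(ValueError):
            condition_index(X, "weighted")
        with pytest.raises(ValueError):
            condition_index(X, "correlation_full")
        with pytest.raises(ValueError):
            condition_index(X, "no_such_convention")
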