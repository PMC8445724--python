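"""The Poisson Liu estimator and its hat matrix and residuals.

The Liu estimator shrinks the ML solution towards the origin to stabilise
it under multicollinearity:

    beta_d = (X'WX + I)^{-1} (X'WX + d I) beta_ML,     0 <= d <= 1,

with W frozen at the converged IRLS weights (a one-shot transform of the
ML fit, no re-iteration).  ``d = 1`` recovers the ML estimator exactly.
In the eigenbasis of ``S = X'WX`` each rotated coefficient ``alpha_j`` is
multiplied by ``(lambda_j + d)/(lambda_j + 1)``, which is where the
data-driven selection rules for ``d`` come from.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .glm import PoissonRegression, RankDeficientDesignError, _design

__all__ = [
    "LiuPoissonRegression",
    "liu_fit",
    "select_d",
    "hat_matrix_liu",
    "leverages_liu",
    "residuals_liu",
]


def _eigen(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, Q = np.linalg.eigh(S)
    if lam[0] <= 0:
        raise RankDeficientDesignError("X'WX is not positive definite")
    return lam, Q


def _d_from_rule(lam: np.ndarray, alpha: np.ndarray, rule: str) -> float:
    """Shrinkage parameter from the eigen-structure of X'WX.

    ``d1`` uses m_j = (alpha_j^2 - 1)/(1/lambda_j + alpha_j^2); ``d2``
    replaces the alpha_j^2 in the denominator by max_j alpha_j^2.  Both are
    floored at 0 and, because the estimator is defined on [0, 1], capped
    at 1.
    """
    a2 = alpha**2
    if rule == "d1":
        crit = (a2 - 1.0) / (1.0 / lam + a2)
    elif rule == "d2":
        crit = (a2 - 1.0) / (1.0 / lam + np.max(a2))
    else:
        raise ValueError(f"unknown d rule {rule!r}; use 'd1' or 'd2'")
    return float(np.clip(np.min(crit), 0.0, 1.0))


class LiuPoissonRegression(RegressorMixin, BaseEstimator):
    """Poisson regression with Liu shrinkage of the ML coefficients.

    Parameters
    ----------
    d : {'d1', 'd2'} or float in [0, 1], default 'd1'
        Shrinkage parameter, either selected by one of the two data-driven
        rules or fixed.
    shrink_intercept : bool, default True
        Shrink the full coefficient vector, intercept included.  With
        ``False`` only the slopes are shrunk and the intercept is
        recentred by a final ML step on the offsetted problem kept simple:
        the intercept coefficient is left at its ML value.
    fit_intercept, tol, max_iter
        Passed to the underlying :class:`PoissonRegression`.

    Attributes
    ----------
    d_ : selected/fixed shrinkage parameter.
    d_rule_ : 'd1', 'd2' or 'fixed'.
    beta_, coef_, intercept_ : Liu coefficients.
    mu_ : Liu fitted means on the training data.
    eigenvalues_ : eigenvalues of X'WX, descending.
    alpha_ : rotated ML coefficients in the eigenbasis (same order).
    base_ : the converged ML :class:`PoissonRegression` being shrunk.
    """

    def __init__(
        self,
        d="d1",
        shrink_intercept: bool = True,
        fit_intercept: bool = True,
        tol: float = 1e-8,
        max_iter: int = 50,
    ):
        self.d = d
        self.shrink_intercept = shrink_intercept
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, base: PoissonRegression | None = None):
        if base is None:
            base = PoissonRegression(
                fit_intercept=self.fit_intercept, tol=self.tol, max_iter=self.max_iter
            ).fit(X, y)
        if not base.converged_:
            raise RuntimeError("underlying IRLS fit did not converge")
        A = _design(np.asarray(X, dtype=float), base.fit_intercept)
        S = A.T @ (base.weights_[:, None] * A)
        lam, Q = _eigen(S)
        alpha = Q.T @ base.beta_

        if isinstance(self.d, str):
            d_val = _d_from_rule(lam, alpha, self.d)
            self.d_rule_ = self.d
        else:
            d_val = float(self.d)
            if not 0.0 <= d_val <= 1.0:
                raise ValueError(f"d must lie in [0, 1], got {d_val}")
            self.d_rule_ = "fixed"

        shrink = (lam + d_val) / (lam + 1.0)
        if self.shrink_intercept or not base.fit_intercept:
            beta_d = Q @ (shrink * alpha)
        else:
            # shrink in the eigenbasis of the slope block only
            S_s = S[1:, 1:]
            lam_s, Q_s = _eigen(S_s)
            a_s = Q_s.T @ base.beta_[1:]
            beta_d = base.beta_.copy()
            beta_d[1:] = Q_s @ ((lam_s + d_val) / (lam_s + 1.0) * a_s)
        self.d_ = d_val
        self.beta_ = beta_d
        if base.fit_intercept:
            self.intercept_ = float(beta_d[0])
            self.coef_ = beta_d[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta_d.copy()
        self.mu_ = np.exp(A @ beta_d)
        self.eigenvalues_ = lam[::-1].copy()
        self.alpha_ = alpha[::-1].copy()
        self.base_ = base
        self.n_features_in_ = np.atleast_2d(np.asarray(X)).shape[1]
        self._S = S
        return self

    def predict(self, X):
        check_is_fitted(self, "beta_")
        X = check_array(X, dtype=float)
        return np.exp(_design(X, self.base_.fit_intercept) @ self.beta_)


def liu_fit(base: PoissonRegression, X, y, d: float) -> LiuPoissonRegression:
    """Shrink a converged ML fit with a fixed ``d``."""
    model = LiuPoissonRegression(d=d, fit_intercept=base.fit_intercept)
    return model.fit(X, y, base=base)


def select_d(base: PoissonRegression, X, rule: str = "d1") -> float:
    """Data-driven Liu parameter from the eigen-structure of X'WX."""
    A = _design(np.asarray(X, dtype=float), base.fit_intercept)
    S = A.T @ (base.weights_[:, None] * A)
    lam, Q = _eigen(S)
    return _d_from_rule(lam, Q.T @ base.beta_, rule)


def hat_matrix_liu(model: LiuPoissonRegression, X) -> np.ndarray:
    """Liu hat matrix, in the symmetric sandwich form.

    ``H_d = W^{1/2} X (X'WX+I)^{-1} (X'WX+dI) (X'WX)^{-1} X' W^{1/2}``.
    Not a projection for ``d < 1``; its trace is
    ``sum_j (lambda_j + d)/(lambda_j + 1)`` and it reduces to the ML hat
    matrix at ``d = 1``.
    """
    check_is_fitted(model, "beta_")
    base = model.base_
    A = _design(np.asarray(X, dtype=float), base.fit_intercept)
    K = np.sqrt(base.weights_)[:, None] * A
    S = model._S
    q = S.shape[0]
    Iq = np.eye(q)
    try:
        inner = np.linalg.solve(S + Iq, S + model.d_ * Iq) @ np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientDesignError("singular weighted cross-product X'WX") from exc
    H = K @ inner @ K.T
    return 0.5 * (H + H.T)


def leverages_liu(model: LiuPoissonRegression, X) -> np.ndarray:
    """Diagonal of the Liu hat matrix."""
    return np.diag(hat_matrix_liu(model, X)).copy()


def residuals_liu(
    model: LiuPoissonRegression, X, y
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson, standardized, and deviance residuals of the Liu fit.

    Same conventions as the ML residuals with ``mu_d`` and the Liu
    leverages substituted.
    """
    y = np.asarray(y, dtype=float)
    mu_d = model.predict(X)
    h_d = leverages_liu(model, X)
    chi = (y - mu_d) / np.sqrt(mu_d)
    with np.errstate(divide="ignore", invalid="ignore"):
        standardized = np.where(
            h_d < 1.0, chi / np.sqrt(np.clip(1.0 - h_d, 0.0, None)), np.inf * np.sign(chi)
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ylog = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu_d), 0.0)
    dev = np.sign(y - mu_d) * np.sqrt(np.maximum(2.0 * (ylog - (y - mu_d)), 0.0))
    return chi, standardized, dev
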