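"""Poisson regression by iteratively reweighted least squares (IRLS).

The model is the canonical log-link Poisson GLM: counts ``y_i`` with mean
``mu_i = exp(x_i' beta)``.  Fisher scoring solves the score equations by
repeated weighted least-squares solves with weights ``W = diag(mu)`` and
working response ``z_i = log(mu_i) + (y_i - mu_i)/mu_i``.

The module also exposes the quantities influence analysis is built on: the
weighted hat matrix ``H = W^{1/2} X (X'WX)^{-1} X' W^{1/2}``, its diagonal
(leverages), Pearson / standardized / deviance residuals, and the condition
index used to gauge multicollinearity of the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "ModelData",
    "PoissonRegression",
    "RankDeficientDesignError",
    "irls_fit",
    "hat_matrix",
    "leverages",
    "residuals",
    "pearson_ratio",
    "condition_index",
    "poisson_loglik",
    "poisson_deviance",
]

# Linear predictors beyond this magnitude make exp() meaningless in double
# precision; treated as divergence of the scoring iteration.
_ETA_MAX = 500.0


class RankDeficientDesignError(np.linalg.LinAlgError):
    """Raised when the weighted cross-product X'WX is singular."""


@dataclass
class ModelData:
    """A count response with its regressor matrix.

    Parameters
    ----------
    y : array-like of shape (n,)
        Nonnegative integer counts.
    X : array-like of shape (n, p)
        Regressors, excluding the intercept column.
    add_intercept : bool, default True
        Whether model fits prepend a constant column.
    names : list of str, optional
        Regressor labels; defaults to ``x1..xp``.
    """

    y: np.ndarray
    X: np.ndarray
    add_intercept: bool = True
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.y.ndim != 1 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("y must be 1-d with one entry per row of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise ValueError("y must contain nonnegative integer counts")
        n, p = self.X.shape
        if self.add_intercept and n <= p + 1:
            raise ValueError(f"need n > p+1 ({n} rows, {p} regressors)")
        if not self.names:
            self.names = [f"x{j + 1}" for j in range(p)]
        elif len(self.names) != p:
            raise ValueError("names must match the number of regressors")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        """Number of regressors, excluding the intercept."""
        return self.X.shape[1]

    @property
    def design(self) -> np.ndarray:
        """The design matrix actually fitted (intercept first, if any)."""
        if self.add_intercept:
            return np.column_stack([np.ones(self.n), self.X])
        return self.X


def _design(X: np.ndarray, fit_intercept: bool) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if fit_intercept:
        return np.column_stack([np.ones(X.shape[0]), X])
    return X


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood up to and including the log y! term."""
    from scipy.special import gammaln

    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Model deviance, with the ``y log(y/mu) -> 0`` convention at y = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ylog = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return float(2.0 * np.sum(ylog - (y - mu)))


class PoissonRegression(RegressorMixin, BaseEstimator):
    """Canonical-link Poisson regression fitted by IRLS.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend a constant column to the design.
    tol : float, default 1e-8
        Convergence tolerance on the max absolute coefficient change.
    max_iter : int, default 50
        Maximum Fisher-scoring iterations.

    Attributes
    ----------
    beta_ : ndarray of shape (p'+,)
        Full coefficient vector, intercept first when fitted.
    coef_, intercept_ : slope / intercept views of ``beta_``.
    mu_ : fitted means on the training data.
    weights_ : IRLS weights at convergence (``mu_`` for the canonical link).
    working_response_ : working response ``z`` at convergence.
    loglik_, deviance_ : maximized log-likelihood and model deviance.
    n_iter_, converged_ : iteration count and convergence flag.

    Notes
    -----
    The scoring iteration starts from ``mu = y + 0.5`` (guards ``log 0``).
    Non-convergence is not an exception: the estimator keeps the last
    iterate and sets ``converged_ = False``.
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8, max_iter: int = 50):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_features=0)
        if np.any(y < 0):
            raise ValueError("Poisson responses must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        A = _design(X, self.fit_intercept)
        n, q = A.shape
        if n <= q:
            raise ValueError(f"need more observations ({n}) than coefficients ({q})")

        mu = y + 0.5
        eta = np.log(mu)
        beta = np.linalg.lstsq(A, eta, rcond=None)[0]
        converged = False
        loglik_prev = -np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = A @ beta
            if np.max(np.abs(eta)) > _ETA_MAX:
                break
            mu = np.exp(eta)
            z = eta + (y - mu) / mu
            S = A.T @ (mu[:, None] * A)
            try:
                beta_new = np.linalg.solve(S, A.T @ (mu * z))
            except np.linalg.LinAlgError as exc:
                if it == 1:
                    raise RankDeficientDesignError(
                        "singular weighted cross-product X'WX"
                    ) from exc
                break  # weights degenerated mid-iteration: report divergence
            if not np.all(np.isfinite(beta_new)):
                break
            step = float(np.max(np.abs(beta_new - beta)))
            beta = beta_new
            ll = poisson_loglik(y, np.exp(np.clip(A @ beta, -_ETA_MAX, _ETA_MAX)))
            if ll < loglik_prev - 1e-8:
                warnings.warn(
                    "log-likelihood decreased during IRLS; fit may be unstable",
                    RuntimeWarning,
                    stacklevel=2,
                )
            loglik_prev = ll
            if step < self.tol:
                converged = True
                break

        eta = np.clip(A @ beta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        self.beta_ = beta
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.mu_ = mu
        self.weights_ = mu.copy()
        self.working_response_ = eta + (y - mu) / mu
        self.loglik_ = poisson_loglik(y, mu)
        self.deviance_ = poisson_deviance(y, mu)
        self.n_iter_ = it
        self.converged_ = converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "beta_")
        X = check_array(X, dtype=float, ensure_min_features=0)
        return np.exp(_design(X, self.fit_intercept) @ self.beta_)

    def information_matrix(self, X) -> np.ndarray:
        """Observed/expected information ``X'WX`` at the fitted weights."""
        check_is_fitted(self, "beta_")
        A = _design(X, self.fit_intercept)
        return A.T @ (self.weights_[:, None] * A)


def irls_fit(
    data: ModelData, tol: float = 1e-8, max_iter: int = 50
) -> PoissonRegression:
    """Fit ``data`` by IRLS and return the fitted estimator."""
    model = PoissonRegression(fit_intercept=data.add_intercept, tol=tol, max_iter=max_iter)
    return model.fit(data.X, data.y)


def hat_matrix(model: PoissonRegression, X) -> np.ndarray:
    """Weighted hat matrix ``H = W^{1/2} X (X'WX)^{-1} X' W^{1/2}``.

    Symmetric and idempotent with trace equal to the number of fitted
    coefficients.
    """
    check_is_fitted(model, "beta_")
    A = _design(X, model.fit_intercept)
    K = np.sqrt(model.weights_)[:, None] * A
    S = K.T @ K
    try:
        return K @ np.linalg.solve(S, K.T)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientDesignError("singular weighted cross-product X'WX") from exc


def leverages(model: PoissonRegression, X) -> np.ndarray:
    """Diagonal of the hat matrix without forming the full n x n matrix."""
    check_is_fitted(model, "beta_")
    A = _design(X, model.fit_intercept)
    K = np.sqrt(model.weights_)[:, None] * A
    S = K.T @ K
    try:
        return np.einsum("ij,ij->i", K, np.linalg.solve(S, K.T).T)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientDesignError("singular weighted cross-product X'WX") from exc


def residuals(
    model: PoissonRegression, X, y
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson, standardized-Pearson, and deviance residuals.

    Pearson residuals are ``(y - mu)/sqrt(mu)``; standardization divides by
    ``sqrt(1 - h)``; an observation with leverage one gets an infinite
    standardized residual rather than an exception.  Deviance residuals are
    signed square roots of per-observation deviance contributions, so their
    squares sum to the model deviance.
    """
    y = np.asarray(y, dtype=float)
    mu = model.predict(X)
    h = leverages(model, X)
    chi = (y - mu) / np.sqrt(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        standardized = np.where(h < 1.0, chi / np.sqrt(np.clip(1.0 - h, 0.0, None)), np.inf * np.sign(chi))
    with np.errstate(divide="ignore", invalid="ignore"):
        ylog = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    dev = np.sign(y - mu) * np.sqrt(np.maximum(2.0 * (ylog - (y - mu)), 0.0))
    return chi, standardized, dev


def pearson_ratio(model: PoissonRegression, X, y) -> np.ndarray:
    """The raw ratio ``(y - mu)/mu`` (relative error on the mean scale)."""
    y = np.asarray(y, dtype=float)
    mu = model.predict(X)
    return (y - mu) / mu


_CI_CONVENTIONS = ("correlation", "raw", "weighted", "correlation_full")


def condition_index(
    X,
    convention: str = "correlation",
    y=None,
    weights=None,
) -> float:
    """Condition index ``sqrt(lambda_max / lambda_min)`` of a cross-product.

    Parameters
    ----------
    X : array-like of shape (n, p)
        Regressor matrix (no intercept column).
    convention : str
        ``"correlation"`` — eigenvalues of the regressor correlation matrix
        (centred and scaled columns, no intercept; the textbook default);
        ``"raw"`` — raw ``X'X`` with an intercept column;
        ``"weighted"`` — ``X'WX`` with an intercept column, requires
        ``weights``;
        ``"correlation_full"`` — correlation matrix of the response together
        with the regressors, requires ``y``.
    y, weights : array-like, optional
        Response / IRLS weights for the conventions that need them.

    Returns
    -------
    float
        Condition index, at least 1.  Values above roughly 30 are the
        usual signal of harmful multicollinearity.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if convention == "correlation":
        M = np.corrcoef(X, rowvar=False)
    elif convention == "raw":
        A = np.column_stack([np.ones(n), X])
        M = A.T @ A
    elif convention == "weighted":
        if weights is None:
            raise ValueError("convention 'weighted' requires IRLS weights")
        w = np.asarray(weights, dtype=float)
        A = np.column_stack([np.ones(n), X])
        M = A.T @ (w[:, None] * A)
    elif convention == "correlation_full":
        if y is None:
            raise ValueError("convention 'correlation_full' requires y")
        M = np.corrcoef(np.column_stack([np.asarray(y, dtype=float), X]), rowvar=False)
    else:
        raise ValueError(f"unknown convention {convention!r}; choose from {_CI_CONVENTIONS}")
    ev = np.linalg.eigvalsh(M)
    lam_min, lam_max = float(ev[0]), float(ev[-1])
    if lam_min <= max(1e-12 * lam_max, 0.0):
        raise RankDeficientDesignError("cross-product matrix is (near-)singular: exact collinearity")
    return float(np.sqrt(lam_max / lam_min))
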