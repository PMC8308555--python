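"""Small regression cores used throughout the package.

The logistic solver is a hand-rolled Newton/IRLS with the convergence
contract the association engine documents (relative log-likelihood change
below 1e-10 or 50 iterations; separation declared when a coefficient
exceeds 30 in absolute value).  It is cross-checked against
statsmodels' Logit in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .containers import ConvergenceError, SeparationError, ValidationError

MAX_ITER = 50
REL_LL_TOL = 1e-10
SEPARATION_BOUND = 30.0


@dataclass
class FitResult:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray          # two-sided Wald p-values
    n: int
    loglik: float | None = None
    n_iter: int | None = None
    sigma2: float | None = None   # OLS residual variance
    r2: float | None = None       # OLS coefficient of determination


def check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise naming the offending columns when X is rank deficient."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if names is None:
            names = [f"col{j}" for j in range(X.shape[1])]
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(X.shape[1]):
            Xj = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xj) == rank:
                collinear.append(names[j])
        raise ValidationError(
            f"design matrix rank deficient; collinear columns: {collinear}")


def fit_ols(X: np.ndarray, y: np.ndarray,
            names: list[str] | None = None) -> FitResult:
    """Ordinary least squares with t-based two-sided p-values."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValidationError(f"need n > {k} observations, got {n}")
    check_full_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return FitResult(beta=beta, se=se, p=p, n=n, sigma2=sigma2, r2=r2)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(X: np.ndarray, y: np.ndarray,
                 names: list[str] | None = None,
                 max_iter: int = MAX_ITER,
                 tol: float = REL_LL_TOL) -> FitResult:
    """Maximum-likelihood logistic regression via Newton/IRLS.

    Raises
    ------
    SeparationError
        when any coefficient diverges past +/-30 (complete separation).
    ConvergenceError
        when the relative log-likelihood change stays above ``tol``
        after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("outcome has a single class; logistic fit undefined")
    check_full_rank(X, names)
    n, k = X.shape
    beta = np.zeros(k)
    ll = _loglik(y, X @ beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix at iteration {n_iter} "
                f"(max |beta| = {np.abs(beta).max():.2f})") from exc
        # step-halving to keep the likelihood non-decreasing
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.abs(beta).max() > SEPARATION_BOUND:
            raise SeparationError(
                f"coefficient exceeded {SEPARATION_BOUND} "
                f"(|beta|max = {np.abs(beta).max():.1f}); "
                "data likely separated")
        rel = abs(ll_new - ll) / (abs(ll) + 1e-300)
        ll = ll_new
        if rel < tol:
            break
    else:
        raise ConvergenceError(
            f"logistic fit not converged after {max_iter} iterations "
            f"(relative LL change {rel:.2e})")
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return FitResult(beta=beta, se=se, p=p, n=n, loglik=ll, n_iter=n_iter)


def design_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    """Intercept + optional covariate block as a float matrix.

    ``covariates`` may be None, a DataFrame, or a 2-D array.  Categorical
    / object DataFrame columns are dummy-encoded (first level dropped).
    """
    import pandas as pd

    if covariates is None:
        return np.ones((n, 1)), ["const"]
    if isinstance(covariates, pd.DataFrame):
        enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
        X = enc.to_numpy(dtype=float)
        names = ["const"] + list(enc.columns)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = ["const"] + [f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] != n:
        raise ValidationError(
            f"covariate rows ({X.shape[0]}) != observations ({n})")
    return np.column_stack([np.ones(n), X]), names
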