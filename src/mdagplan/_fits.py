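"""Small dense-regression kernels used inside imputation and analysis loops.

These are deliberately minimal (QR/Cholesky least squares, Newton-Raphson
logistic regression) because the chained-equations sampler fits thousands of
models per run; each returns exactly what proper imputation needs — point
estimates plus the pieces of the parameter posterior.  The public analysis
surface is cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .errors import ImputationModelError, InsufficientDataError


def add_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def ols(X: np.ndarray, y: np.ndarray):
    """Least squares with classical covariance pieces.

    Returns (beta, sigma2_hat, XtX_inv, df_resid).
    """
    n, p = X.shape
    if n < p + 1:
        raise InsufficientDataError(f"{n} rows for {p} parameters")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise InsufficientDataError("singular design matrix") from None
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    return beta, sigma2, xtx_inv, df


def ols_posterior_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Proper-imputation parameter draw under the standard noninformative prior.

    sigma² is drawn from its scaled inverse-chi-square posterior, beta from
    N(beta_hat, sigma²·(X'X)⁻¹).  Returns (beta_draw, sigma_draw).
    """
    beta, sigma2, xtx_inv, df = ols(X, y)
    sigma2_draw = sigma2 * df / rng.chisquare(df)
    try:
        L = np.linalg.cholesky(xtx_inv)
    except np.linalg.LinAlgError:
        raise ImputationModelError("non-positive-definite design covariance") from None
    beta_draw = beta + np.sqrt(sigma2_draw) * (L @ rng.standard_normal(len(beta)))
    return beta_draw, float(np.sqrt(sigma2_draw))


def logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Newton-Raphson logistic regression.

    Returns (beta, cov).  Raises :class:`ImputationModelError` on failure to
    converge or on a singular information matrix (the usual symptom of
    complete separation).
    """
    n, p = X.shape
    if n < p + 1:
        raise ImputationModelError(f"{n} rows for {p} logistic parameters")
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        # guard against exactly-saturated weights
        w = np.maximum(w, 1e-12)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise ImputationModelError("singular information matrix in logistic fit") from None
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ImputationModelError("logistic fit did not converge (possible separation)")
    if np.max(np.abs(beta)) > 30.0:
        raise ImputationModelError("diverging logistic coefficients (possible separation)")
    mu = expit(X @ beta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ImputationModelError("singular information matrix in logistic fit") from None
    return beta, cov


def logistic_posterior_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Large-sample normal approximation to the logistic coefficient posterior."""
    beta, cov = logistic(X, y)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # fall back to a symmetric eigendecomposition square root
        vals, vecs = np.linalg.eigh(cov)
        L = vecs @ np.diag(np.sqrt(np.maximum(vals, 0.0)))
    return beta + L @ rng.standard_normal(len(beta))
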