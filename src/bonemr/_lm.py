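"""Small linear-model core used by the estimators.

The hot simulation loops (calibration tests run thousands of replicates) need
OLS fits without per-call model-object overhead, so the package carries a thin
QR-based least-squares kernel.  Everything here is cross-checked against
statsmodels in the test suite; user-facing single fits go through statsmodels
where a practitioner would reach for it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError


@dataclass
class OLSFit:
    """Minimal OLS fit: coefficients, classical covariance, residuals."""

    beta: np.ndarray          # (k,)
    cov: np.ndarray           # (k, k) classical sigma^2 (X'X)^-1
    resid: np.ndarray         # (n,)
    rss: float
    df_resid: int
    sigma2: float             # rss / df_resid

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def t_pvalues(self) -> np.ndarray:
        t = self.beta / self.se
        return 2.0 * stats.t.sf(np.abs(t), self.df_resid)


def ols(y: np.ndarray, X: np.ndarray) -> OLSFit:
    """Classical OLS of ``y`` on design ``X`` (caller supplies the intercept).

    Raises :class:`DegenerateDataError` if the design is rank-deficient.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X have different numbers of rows")
    n, k = X.shape
    if n <= k:
        raise DegenerateDataError(f"n={n} observations for k={k} parameters")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise DegenerateDataError("rank-deficient design matrix")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    Rinv = np.linalg.solve(R, np.eye(k))
    cov = sigma2 * (Rinv @ Rinv.T)
    return OLSFit(beta=beta, cov=cov, resid=resid, rss=rss, df_resid=df, sigma2=sigma2)


def add_constant(*cols: np.ndarray, n: int | None = None) -> np.ndarray:
    """Column-stack a leading intercept with any number of regressors.

    Each element of ``cols`` may be 1-D ``(n,)`` or 2-D ``(n, k)``; ``n`` is
    only required when no columns are given.
    """
    mats = []
    for c in cols:
        c = np.asarray(c, dtype=float)
        mats.append(c[:, None] if c.ndim == 1 else c)
    if mats:
        n = mats[0].shape[0]
    if n is None:
        raise ValueError("n required when no columns are given")
    return np.column_stack([np.ones(n)] + mats)


def partial_f(y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray) -> tuple[float, float, float]:
    """Partial F test of the block present in ``X_full`` but not ``X_reduced``.

    Returns ``(F, p, incremental_r2)`` where the incremental R^2 is relative
    to the total sum of squares of ``y`` about its mean.
    """
    fit_f = ols(y, X_full)
    fit_r = ols(y, X_reduced)
    q = X_full.shape[1] - X_reduced.shape[1]
    if q <= 0:
        raise ValueError("X_full must strictly extend X_reduced")
    F = (fit_r.rss - fit_f.rss) / q / fit_f.sigma2
    F = max(F, 0.0)
    p = float(stats.f.sf(F, q, fit_f.df_resid))
    tss = float(np.sum((np.asarray(y, float) - np.mean(y)) ** 2))
    inc_r2 = (fit_r.rss - fit_f.rss) / tss if tss > 0 else 0.0
    return float(F), p, float(inc_r2)


def standardize(x: np.ndarray, name: str = "variable") -> np.ndarray:
    """Center and scale to unit sample SD (ddof=1); error on zero variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateDataError(f"zero-variance {name}")
    return (x - x.mean()) / sd


def wls(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> OLSFit:
    """Weighted least squares with estimated scale (statsmodels WLS default).

    Equivalent to OLS on sqrt(w)-scaled data; standard errors use the
    weighted residual variance with n - k degrees of freedom.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    sw = np.sqrt(w)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(w):
        X = X.T
    return ols(np.asarray(y, float) * sw, X * sw[:, None])


def residualize(M: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``M`` after OLS on ``W`` (shared QR)."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    Q, _ = np.linalg.qr(np.asarray(W, dtype=float))
    return M - Q @ (Q.T @ M)
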