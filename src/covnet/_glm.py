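"""Vectorized ordinary-least-squares helpers shared by the estimators.

All fits here solve the normal equations for one design matrix against
one or many response columns, which is what makes whole-brain maps and
permutation nulls affordable: a seed-to-brain fit is a single (n x p)
design solved against tens of thousands of target columns at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def add_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """[1, covariates] design block; covariates may be None/empty."""
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match the number of subjects")
    return np.column_stack([np.ones(n), C])


def check_full_rank(X: np.ndarray, what: str = "design matrix") -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"{what} is rank deficient")


@dataclass
class OLSFit:
    """OLS estimates for one design against one or many responses.

    ``params``/``bse``/``tvalues``/``pvalues`` have shape (p,) for a 1D
    response and (p, m) for an (n, m) response block.
    """

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    resid: np.ndarray
    df_resid: int
    ssr: np.ndarray


def ols(X: np.ndarray, Y: np.ndarray, check_rank: bool = True) -> OLSFit:
    """Fit Y = X b by least squares with Student-t inference per column."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("response rows do not match design rows")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    if check_rank:
        check_full_rank(X)

    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n - p
    ssr = np.einsum("nm,nm->m", resid, resid)
    sigma2 = ssr / df
    xtx_inv = np.linalg.inv(X.T @ X)
    var = np.outer(np.diag(xtx_inv), sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        bse = np.sqrt(var)
        tvals = np.where(bse > 0, beta / np.where(bse > 0, bse, 1.0), np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    if squeeze:
        beta, bse, tvals, pvals = beta[:, 0], bse[:, 0], tvals[:, 0], pvals[:, 0]
        resid, ssr = resid[:, 0], float(ssr[0])
    return OLSFit(params=beta, bse=bse, tvalues=tvals, pvalues=pvals, resid=resid, df_resid=df, ssr=ssr)


def residual_variance(ssr: np.ndarray | float, n_eff: int) -> np.ndarray | float:
    """Residual variance as mean squared residual (same divisor for nested fits)."""
    return ssr / n_eff


def corr_pvalues(r: np.ndarray, df: int) -> np.ndarray:
    """Two-tailed Student-t p for correlations via t = r sqrt(df/(1-r^2))."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    if df <= 0:
        raise ValueError("non-positive degrees of freedom for the correlation test")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df)
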