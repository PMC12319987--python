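"""Minimal multi-response OLS used across the package.

A thin least-squares layer (numpy/scipy) so that per-network regressions can
be vectorized across networks and Monte-Carlo replicates; unit tests check it
against statsmodels OLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OLSFit", "ols_fit", "design_with_intercept"]


@dataclass
class OLSFit:
    """coef/se/t/p have shape (n_params, n_responses); resid (n_obs, n_responses)."""

    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    resid: np.ndarray
    df_resid: int


def design_with_intercept(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(X.shape[0]), X])


def ols_fit(X: np.ndarray, Y: np.ndarray) -> OLSFit:
    """OLS of each column of Y on the design X (X includes any intercept)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular design matrix") from exc
    coef = xtx_inv @ X.T @ Y
    resid = Y - X @ coef
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return OLSFit(coef=coef, se=se, t=t, p=p, resid=resid, df_resid=df)
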