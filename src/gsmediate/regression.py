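"""Closed-form OLS fits of the three analysis models.

The three regressions run at every (interim or final) analysis are

* total-effect model:   Y ~ 1 + X          (theta = coefficient on X)
* mediator model:       M ~ 1 + X          (a)
* outcome model:        Y ~ 1 + X + M      (c', b)

All are ordinary least squares with homoskedastic standard errors and t-based
two-sided p-values.  Because the three fits use the same records, the product
method identity ``theta_hat = c'_hat + a_hat * b_hat`` holds to machine
precision on every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import stdtr

__all__ = [
    "FitResult",
    "fit_total_model",
    "fit_mediator_model",
    "fit_outcome_model",
]


@dataclass(frozen=True)
class FitResult:
    """Per-coefficient OLS output plus residual variance."""

    names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    resid_var: float
    nobs: int
    cov_params: np.ndarray

    def __getitem__(self, name: str) -> dict[str, float]:
        i = self.names.index(name)
        return {
            "estimate": float(self.params[i]),
            "se": float(self.bse[i]),
            "t": float(self.tvalues[i]),
            "p": float(self.pvalues[i]),
        }

    def estimate(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return (
            data["arm"].to_numpy(dtype=float),
            data["mediator"].to_numpy(dtype=float),
            data["outcome"].to_numpy(dtype=float),
        )
    x, m, y = data
    return np.asarray(x, float), np.asarray(m, float), np.asarray(y, float)


def _ols(X: np.ndarray, y: np.ndarray, names: tuple[str, ...]) -> FitResult:
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} observations, got {n}")
    xtx = X.T @ X
    # rank / conditioning guard (collinear mediator, single-arm data, ...)
    if np.linalg.matrix_rank(xtx) < k or np.linalg.cond(xtx) > 1e12:
        raise np.linalg.LinAlgError("singular design matrix")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    s2 = float(resid @ resid) / df
    cov = s2 * xtx_inv
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stdtr(df, -np.abs(tvals))
    return FitResult(
        names=names,
        params=beta,
        bse=se,
        tvalues=tvals,
        pvalues=pvals,
        df_resid=df,
        resid_var=s2,
        nobs=n,
        cov_params=cov,
    )


def _check_both_arms(x: np.ndarray) -> None:
    if x.min() == x.max():
        raise ValueError("degenerate design: only one arm present in the data")


def fit_total_model(data) -> FitResult:
    """OLS of the outcome on intercept + arm; the arm coefficient is the
    intention-to-treat (total) effect estimate, equal to the difference in
    arm means."""
    x, _, y = _as_arrays(data)
    _check_both_arms(x)
    X = np.column_stack([np.ones_like(x), x])
    return _ols(X, y, ("intercept", "theta"))


def fit_mediator_model(data) -> FitResult:
    """OLS of the mediator on intercept + arm (the X -> M path, ``a``)."""
    x, m, _ = _as_arrays(data)
    _check_both_arms(x)
    X = np.column_stack([np.ones_like(x), x])
    return _ols(X, m, ("intercept", "a"))


def fit_outcome_model(data) -> FitResult:
    """OLS of the outcome on intercept + arm + mediator (``c'`` and ``b``)."""
    x, m, y = _as_arrays(data)
    _check_both_arms(x)
    X = np.column_stack([np.ones_like(x), x, m])
    return _ols(X, y, ("intercept", "c_prime", "b"))
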