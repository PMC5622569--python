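"""Full four-parameter model refits for triples that survive the screen.

The screen reports only the interaction p-value.  Once the survivors are
known, this module fits y = b0 + b1*x + b2*z + b3*x*z + e by ordinary least
squares (QR decomposition) to recover effect estimates, standard errors and
goodness of fit — the standard two-phase workflow for genome-scale scans.
It doubles as the brute-force oracle against which the screen's shortcut is
verified: for every nondegenerate triple the b3 p-value here must equal the
screen's p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import InputError

__all__ = [
    "FullModelFit",
    "fit_full_model",
    "adjusted_r_squared",
    "compare_with_without_interaction",
]


@dataclass
class FullModelFit:
    """OLS fit of y ~ 1 + x + z + x*z for a single triple."""

    beta: np.ndarray          # (b0, b1, b2, b3)
    se: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    sigma2: float             # residual variance estimate
    r_squared: float
    adj_r_squared: float
    df_resid: int


def _ols(y: np.ndarray, design: np.ndarray, tol: float):
    """Least squares via QR with a relative rank check on each design column."""
    n, k = design.shape
    Q, R = np.linalg.qr(design)
    col_ss = np.einsum("ij,ij->j", design, design)
    diag = np.abs(np.diag(R))
    if np.any(diag * diag <= tol * np.maximum(col_ss, np.finfo(float).tiny)):
        raise InputError("rank-deficient design: collinear covariates")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - design @ beta
    df_resid = n - k
    sigma2 = float(resid @ resid) / df_resid
    Rinv = np.linalg.solve(R, np.eye(k))
    cov = sigma2 * (Rinv @ Rinv.T)
    se = np.sqrt(np.diag(cov))
    return beta, se, resid, sigma2, df_resid


def fit_full_model(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    tol: float = 1e-12,
) -> FullModelFit:
    """Fit the interaction model for one triple and test each coefficient.

    Coefficient t-tests use n - 4 residual degrees of freedom.  A rank-
    deficient design (e.g. x == z up to affine transformation) raises an
    error, mirroring the triples the screen skips as degenerate.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    n = y.shape[0]
    if x.shape[0] != n or z.shape[0] != n:
        raise InputError("y, x, z must have equal length")
    if n < 5:
        raise InputError(f"need at least 5 observations, got {n}")

    design = np.column_stack([np.ones(n), x, z, x * z])
    beta, se, resid, sigma2, df_resid = _ols(y, design, tol)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = beta / se
    p_values = 2.0 * stats.t.sf(np.abs(t_stats), df_resid)

    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    return FullModelFit(
        beta=beta,
        se=se,
        t_stats=t_stats,
        p_values=p_values,
        sigma2=sigma2,
        r_squared=r2,
        adj_r_squared=adjusted_r_squared(r2, n, 3),
        df_resid=df_resid,
    )


def adjusted_r_squared(r_squared: float, n: int, n_predictors: int) -> float:
    """Coefficient of determination penalized for model size.

    adj R^2 = 1 - (1 - R^2) * (n - 1) / (n - n_predictors - 1).
    """
    if n <= n_predictors + 1:
        raise InputError(
            f"need n > n_predictors + 1 (got n={n}, predictors={n_predictors})"
        )
    return 1.0 - (1.0 - r_squared) * (n - 1) / (n - n_predictors - 1)


def compare_with_without_interaction(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Adjusted R^2 of y ~ 1 + x + z versus y ~ 1 + x + z + x*z.

    Quantifies how much explanatory power the interaction term adds for a
    specific triple.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    n = y.shape[0]

    design_main = np.column_stack([np.ones(n), x, z])
    beta, _, resid, _, _ = _ols(y, design_main, tol)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(resid @ resid)
    r2_main = 1.0 - rss / tss if tss > 0 else 0.0
    r2_main = min(max(r2_main, 0.0), 1.0)
    adj_main = adjusted_r_squared(r2_main, n, 2)

    adj_full = fit_full_model(y, x, z, tol=tol).adj_r_squared
    return adj_main, adj_full
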