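"""Seeded synthetic data with planted interactions, plus statistical validation.

The generator emulates the shape of a multi-omics interaction scan: X plays
the role of methylation-like continuous covariates (or logit-normal beta
values), Z plays SNP dosages coded 0/1/2 under an additive model, and Y holds
continuous outcomes such as residualized metabolite levels.  Planted outcome
columns follow the interaction model y = b0 + b1*x + b2*z + b3*x*z + e with
Gaussian noise; everything else is pure noise, giving a known ground truth for
power and type-I error simulations.

All randomness flows through one explicit numpy Generator — no global state —
so any run is reproducible from its seed, including under parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    InputError,
    NamedMatrix,
    ScreenConfig,
    build_pair_basis,
    center_columns,
    p_from_t,
    partial_correlations,
    t_from_r,
)

__all__ = ["SimConfig", "generate_dataset", "type_i_error_sim", "power_sim"]


@dataclass
class SimConfig:
    """Configuration of a synthetic (X, Y, Z) dataset.

    beta gives (b0, b1, b2, b3) for every planted triple; noise_sd is the
    standard deviation of the Gaussian error.  x_kind selects continuous
    (standard normal), methylation-like (logit-normal in (0,1)) or dosage
    columns; Z is always dosage-coded binomial(2, maf).
    """

    n: int = 100
    p1: int = 10
    p2: int = 10
    p3: int = 10
    beta: tuple[float, float, float, float] = (0.0, 0.2, 0.2, 0.5)
    noise_sd: float = 1.0
    planted: list[tuple[int, int, int]] = field(default_factory=list)
    x_kind: str = "continuous"
    maf: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 5 or min(self.p1, self.p2, self.p3) < 1:
            raise InputError("n >= 5 and positive column counts required")
        if self.noise_sd <= 0:
            raise InputError("noise_sd must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InputError("missing_rate must be in [0, 1)")
        if not (0.0 < self.maf <= 0.5):
            raise InputError("maf must be in (0, 0.5]")
        if self.x_kind not in ("continuous", "dosage", "methylation"):
            raise InputError(f"unknown x_kind: {self.x_kind!r}")
        for xi, yi, zi in self.planted:
            if not (0 <= xi < self.p1 and 0 <= yi < self.p2 and 0 <= zi < self.p3):
                raise InputError(f"planted triple out of range: {(xi, yi, zi)}")


def _draw_x(rng: np.random.Generator, n: int, p: int, kind: str, maf: float) -> np.ndarray:
    if kind == "continuous":
        return rng.standard_normal((n, p))
    if kind == "dosage":
        return rng.binomial(2, maf, size=(n, p)).astype(np.float64)
    # methylation-like beta values in (0, 1)
    return 1.0 / (1.0 + np.exp(-rng.normal(0.0, 1.5, size=(n, p))))


def generate_dataset(cfg: SimConfig) -> tuple[NamedMatrix, NamedMatrix, NamedMatrix]:
    """Generate (X, Y, Z) with the configured planted interaction triples.

    Deterministic given cfg.seed.  Missing cells (NaN) are introduced
    uniformly at random at cfg.missing_rate after the signal is planted.
    """
    rng = np.random.default_rng(cfg.seed)
    X = _draw_x(rng, cfg.n, cfg.p1, cfg.x_kind, cfg.maf)
    Z = rng.binomial(2, cfg.maf, size=(cfg.n, cfg.p3)).astype(np.float64)
    Y = rng.normal(0.0, cfg.noise_sd, size=(cfg.n, cfg.p2))

    b0, b1, b2, b3 = cfg.beta
    for xi, yi, zi in cfg.planted:
        x, z = X[:, xi], Z[:, zi]
        Y[:, yi] += b0 + b1 * x + b2 * z + b3 * x * z

    if cfg.missing_rate > 0:
        for M in (X, Y, Z):
            mask = rng.random(M.shape) < cfg.missing_rate
            # keep at least one observed value per column
            full = mask.all(axis=0)
            mask[0, full] = False
            M[mask] = np.nan

    row_ids = [f"obs{i:04d}" for i in range(cfg.n)]
    return (
        NamedMatrix(X, row_ids, [f"x{j}" for j in range(cfg.p1)]),
        NamedMatrix(Y, row_ids, [f"y{j}" for j in range(cfg.p2)]),
        NamedMatrix(Z, row_ids, [f"z{j}" for j in range(cfg.p3)]),
    )


def _single_triple_pvalue(y, x, z, tol: float = 1e-12) -> float:
    """Interaction p-value for one triple via the orthogonalization shortcut."""
    xc = x - x.mean()
    zc = z - z.mean()
    basis = build_pair_basis(xc, zc, x * z, tol)
    if basis.degenerate:
        return np.nan
    yc = (y - y.mean())[:, None]
    ssy = np.array([float(yc[:, 0] @ yc[:, 0])])
    r = partial_correlations(yc, ssy, basis, tol)[0]
    if np.isnan(r):
        return np.nan
    return p_from_t(t_from_r(r, len(y) - 4), len(y) - 4)


def _replicate_pvalues(X: np.ndarray, Z: np.ndarray, Y: np.ndarray,
                       tol: float = 1e-12) -> np.ndarray:
    """Interaction p-values for replicate-wise triples (column k of each matrix).

    Vectorized mirror of the single-triple shortcut: each replicate's design
    is centered and orthogonalized independently; degenerate replicates get
    NaN.  Used by the Monte-Carlo validators, where every replicate is an
    independent 1x1x1 screen.
    """
    n = X.shape[0]
    df = n - 4
    tiny = np.finfo(float).tiny

    Xc = X - X.mean(axis=0)
    Zc = Z - Z.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    ssx = np.einsum("ij,ij->j", Xc, Xc)
    ok = ssx > tol * np.maximum(np.einsum("ij,ij->j", X, X), tiny)
    q2 = Xc / np.sqrt(np.where(ok, ssx, 1.0))

    ssz = np.einsum("ij,ij->j", Zc, Zc)
    r3 = Zc - q2 * np.einsum("ij,ij->j", Zc, q2)
    ss3 = np.einsum("ij,ij->j", r3, r3)
    ok &= ss3 > tol * np.maximum(ssz, tiny)
    q3 = r3 / np.sqrt(np.where(ok, ss3, 1.0))

    P = X * Z
    P = P - P.mean(axis=0)
    ssp = np.einsum("ij,ij->j", P, P)
    r4 = P - q2 * np.einsum("ij,ij->j", P, q2)
    r4 -= q3 * np.einsum("ij,ij->j", r4, q3)
    ss4 = np.einsum("ij,ij->j", r4, r4)
    ok &= (ss4 > tol * np.maximum(ssp, tiny)) & (ssp > 0)
    q4 = r4 / np.sqrt(np.where(ok, ss4, 1.0))

    ssy = np.einsum("ij,ij->j", Yc, Yc)
    d2 = np.einsum("ij,ij->j", Yc, q2)
    d3 = np.einsum("ij,ij->j", Yc, q3)
    d4 = np.einsum("ij,ij->j", Yc, q4)
    denom_sq = ssy - d2 * d2 - d3 * d3
    ok &= denom_sq > tol * np.maximum(ssy, tiny)

    r = np.where(ok, d4 / np.sqrt(np.where(ok, denom_sq, 1.0)), np.nan)
    np.clip(r, -1.0, 1.0, out=r)
    p = p_from_t(t_from_r(r, df), df)
    return np.where(ok, p, np.nan)


def _simulate_rejection_rate(rng: np.random.Generator, n: int, reps: int,
                             alpha: float, b1: float, b2: float, b3: float,
                             noise_sd: float, x_kind: str, maf: float,
                             batch: int = 2000) -> float:
    rejected = 0
    valid = 0
    done = 0
    while done < reps:
        m = min(batch, reps - done)
        X = _draw_x(rng, n, m, x_kind, maf)
        Z = rng.binomial(2, maf, size=(n, m)).astype(np.float64)
        Y = b1 * X + b2 * Z + b3 * X * Z + rng.normal(0.0, noise_sd, size=(n, m))
        p = _replicate_pvalues(X, Z, Y)
        good = ~np.isnan(p)
        valid += int(good.sum())
        rejected += int((p[good] <= alpha).sum())
        done += m
    return rejected / valid if valid else 0.0


def type_i_error_sim(
    n: int,
    reps: int,
    alpha: float,
    seed: int = 0,
    beta_main: tuple[float, float] = (0.3, 0.3),
    x_kind: str = "continuous",
    maf: float = 0.3,
) -> float:
    """Empirical rejection rate of the interaction test under the null b3 = 0.

    Each replicate draws a fresh (x, z, y) with main effects but no
    interaction and screens it at threshold alpha.  A calibrated test
    rejects at rate alpha up to binomial Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    b1, b2 = beta_main
    return _simulate_rejection_rate(rng, n, reps, alpha, b1, b2, 0.0, 1.0,
                                    x_kind, maf)


def power_sim(
    n: int,
    reps: int,
    alpha: float,
    beta3_grid,
    noise_sd: float = 1.0,
    seed: int = 0,
    x_kind: str = "continuous",
    maf: float = 0.3,
) -> dict[float, float]:
    """Rejection rate of the interaction test for each planted effect size b3.

    At b3 = 0 this reproduces the type-I error rate; the rate is
    non-decreasing in |b3| up to Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    rates: dict[float, float] = {}
    for b3 in beta3_grid:
        rates[float(b3)] = _simulate_rejection_rate(
            rng, n, reps, alpha, 0.3, 0.3, float(b3), noise_sd, x_kind, maf
        )
    return rates
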