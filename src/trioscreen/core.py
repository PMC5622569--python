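"""Exact interaction-term screening via orthogonalization and partial correlation.

For every column triple (x, y, z) drawn from three matrices X, Y, Z the model

    y = b0 + b1*x + b2*z + b3*x*z + e,    e ~ iid N(0, sigma^2)

is tested for H0: b3 = 0.  Instead of fitting each four-parameter model, the
design columns are centered and Gram-Schmidt orthogonalized once per (x, z)
pair; the t statistic of b3 then equals t = r*sqrt(DF/(1-r^2)) where r is the
partial correlation between y and the interaction product x*z given {1, x, z}
and DF = n - 4.  This reproduces the full-model ordinary-least-squares t-test
exactly while the per-outcome work collapses to three inner products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

__all__ = [
    "NamedMatrix",
    "PairBasis",
    "ScreenRecord",
    "ScreenConfig",
    "ScreenResult",
    "center_columns",
    "build_pair_basis",
    "partial_correlations",
    "t_from_r",
    "p_from_t",
    "screen_triples",
    "bonferroni_threshold",
]


class InputError(ValueError):
    """Raised for invalid or inconsistent user inputs."""


@dataclass
class NamedMatrix:
    """An observations x variables numeric matrix with row IDs and column names.

    Rows are observations (samples); columns are variables (e.g. CpG sites,
    metabolites, SNP dosages).  Values must be finite after imputation.
    """

    values: np.ndarray
    row_ids: list[str]
    col_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("matrix values must be two-dimensional")
        n, p = self.values.shape
        if len(self.row_ids) != n:
            raise InputError(f"{len(self.row_ids)} row IDs for {n} rows")
        if len(self.col_names) != p:
            raise InputError(f"{len(self.col_names)} column names for {p} columns")
        if len(set(self.row_ids)) != n:
            raise InputError("row IDs must be unique within a matrix")
        if any(not str(c) for c in self.col_names):
            raise InputError("column names must be non-empty")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class PairBasis:
    """Orthonormalized design columns for one (x, z) covariate pair.

    q2 spans centered x; q3 spans z after removing {1, x}; q4 spans the
    interaction product x*z after removing {1, x, z}.  Together with the
    constant column they form an orthonormal basis of the design span.
    A pair is flagged degenerate when any Gram-Schmidt residual is
    numerically zero relative to the vector being orthogonalized; degenerate
    pairs yield no records and are only counted.
    """

    q2: Optional[np.ndarray]
    q3: Optional[np.ndarray]
    q4: Optional[np.ndarray]
    degenerate: bool
    x_index: int = -1
    z_index: int = -1


@dataclass
class ScreenRecord:
    """One screening hit: the interaction test for a single (x, y, z) triple."""

    x_name: str
    y_name: str
    z_name: str
    r: float
    t: float
    df: int
    p: float
    x_index: int = -1
    y_index: int = -1
    z_index: int = -1


@dataclass
class ScreenConfig:
    """Screening options.

    p_threshold
        Records with p <= p_threshold are emitted (inclusive).  The default
        1.0 emits every testable triple.
    degeneracy_tol
        Relative tolerance: a Gram-Schmidt residual with squared norm
        <= degeneracy_tol * (squared norm of the vector being orthogonalized)
        marks the pair or outcome column as degenerate and it is skipped.
    n_workers
        Number of parallel workers; results are identical for any count.
    emit_statistics
        Whether r, t and df accompany the p-value in written output.
    """

    p_threshold: float = 1.0
    degeneracy_tol: float = 1e-12
    n_workers: int = 1
    output_path: Optional[str] = None
    emit_statistics: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise InputError("p_threshold must be in (0, 1]")
        if self.degeneracy_tol <= 0:
            raise InputError("degeneracy_tol must be positive")
        if self.n_workers < 1:
            raise InputError("n_workers must be a positive integer")


@dataclass
class ScreenResult:
    """Records surviving the threshold plus a summary of skipped work."""

    records: list[ScreenRecord]
    n_candidates: int = 0
    degenerate_pairs: int = 0
    skipped_outcomes: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def center_columns(M: NamedMatrix | np.ndarray):
    """Center each column and cache its mean and centered sum of squares.

    Returns ``(centered, means, sumsq)``.  The sums of squares are reused
    across every (x, z) pair and every outcome, which is the hoisting that
    keeps the inner loop down to three inner products per outcome.
    """
    from ._kernels import _col_means_sumsq

    values = M.values if isinstance(M, NamedMatrix) else np.asarray(M, dtype=np.float64)
    # sequential per-column sums: bit-identical under column partitioning
    means, sumsq = _col_means_sumsq(np.ascontiguousarray(values))
    centered = values - means
    return centered, means, sumsq


def build_pair_basis(
    x_centered: np.ndarray,
    z_centered: np.ndarray,
    xz_raw: np.ndarray,
    tol: float = 1e-12,
    x_index: int = -1,
    z_index: int = -1,
) -> PairBasis:
    """Gram-Schmidt orthonormalization of the design columns for one pair.

    ``xz_raw`` is the elementwise product of the *original* (uncentered) x and
    z columns; it is centered here before orthogonalization.  Degeneracy is a
    flag, never an error, so one collinear pair cannot abort a full run.
    """
    x_centered = np.asarray(x_centered, dtype=np.float64)
    z_centered = np.asarray(z_centered, dtype=np.float64)
    xz_raw = np.asarray(xz_raw, dtype=np.float64)

    ssx = float(x_centered @ x_centered)
    raw_ssx = ssx  # centered input: removing the constant leaves it unchanged
    if ssx <= tol * max(raw_ssx, np.finfo(float).tiny) or ssx == 0.0:
        return PairBasis(None, None, None, True, x_index, z_index)
    q2 = x_centered / math.sqrt(ssx)

    ssz = float(z_centered @ z_centered)
    r3 = z_centered - (z_centered @ q2) * q2
    ss3 = float(r3 @ r3)
    if ssz == 0.0 or ss3 <= tol * ssz:
        return PairBasis(None, None, None, True, x_index, z_index)
    q3 = r3 / math.sqrt(ss3)

    p_centered = xz_raw - xz_raw.mean()
    ssp = float(p_centered @ p_centered)
    r4 = p_centered - (p_centered @ q2) * q2
    r4 -= (r4 @ q3) * q3
    ss4 = float(r4 @ r4)
    if ssp == 0.0 or ss4 <= tol * ssp:
        return PairBasis(None, None, None, True, x_index, z_index)
    q4 = r4 / math.sqrt(ss4)

    return PairBasis(q2, q3, q4, False, x_index, z_index)


def partial_correlations(
    Y_centered: np.ndarray,
    y_sumsq: np.ndarray,
    basis: PairBasis,
    tol: float = 1e-12,
) -> np.ndarray:
    """Partial correlation of each outcome column with the orthogonalized x*z.

    For outcome column j,

        r_j = <y_j, q4> / sqrt(ss_j - <y_j, q2>^2 - <y_j, q3>^2)

    i.e. the correlation between y and x*z with {1, x, z} partialled out of
    both.  Columns whose residual variance vanishes (y lies in span{1, x, z})
    get NaN and are skipped downstream.  The three matrix-vector products are
    the only per-outcome work.
    """
    if basis.degenerate:
        raise ValueError("cannot compute correlations for a degenerate pair")
    d2 = Y_centered.T @ basis.q2
    d3 = Y_centered.T @ basis.q3
    d4 = Y_centered.T @ basis.q4
    denom_sq = y_sumsq - d2 * d2 - d3 * d3
    r = np.full(denom_sq.shape, np.nan)
    ok = denom_sq > tol * np.maximum(y_sumsq, np.finfo(float).tiny)
    r[ok] = d4[ok] / np.sqrt(denom_sq[ok])
    np.clip(r, -1.0, 1.0, out=r)
    return r


def t_from_r(r, df: int):
    """Map a (partial) correlation to the t statistic on ``df`` degrees of freedom.

    t = r * sqrt(df / (1 - r^2)); signed infinity at |r| = 1.
    """
    if df < 1:
        raise InputError("degrees of freedom must be >= 1")
    r = np.asarray(r, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
        t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    return t if t.ndim else float(t)


def p_from_t(t, df: int):
    """Two-sided p-value of a t statistic via the upper-tail survival function.

    Using the survival function keeps precision at extreme t; p(|r|=1) = 0 by
    convention (an exact fit passes any threshold).
    """
    if df < 1:
        raise InputError("degrees of freedom must be >= 1")
    t = np.asarray(t, dtype=np.float64)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.minimum(p, 1.0)
    return p if p.ndim else float(p)


def bonferroni_threshold(alpha: float, designs: Sequence[tuple[int, int, int]]) -> float:
    """Bonferroni-corrected p-value threshold: alpha / total number of tests.

    Each design contributes p1*p2*p3 tests (one per column triple); the
    threshold is alpha divided by the sum over all designs.
    """
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must be in (0, 1)")
    if not designs:
        raise InputError("at least one design is required")
    total = 0
    for dims in designs:
        if len(dims) != 3 or any(int(d) <= 0 for d in dims):
            raise InputError(f"design dimensions must be positive integers: {dims!r}")
        p1, p2, p3 = (int(d) for d in dims)
        total += p1 * p2 * p3
    return alpha / total


def _column_sumsq(A: np.ndarray) -> np.ndarray:
    from ._kernels import _col_sumsq

    return _col_sumsq(np.ascontiguousarray(A))


def _screen_outer_block(
    outer_idx: np.ndarray,
    O_raw: np.ndarray,
    Oc: np.ndarray,
    ss_o: np.ndarray,
    raw_ss_o: np.ndarray,
    I_raw: np.ndarray,
    Ic: np.ndarray,
    ss_i: np.ndarray,
    raw_ss_i: np.ndarray,
    Yc: np.ndarray,
    ss_y: np.ndarray,
    df: int,
    threshold: float,
    tol: float,
):
    """Screen every (outer, inner) covariate pair for a block of outer columns.

    The outer matrix is whichever of X/Z has more columns (work partitioning
    happens over it); "inner" is the other.  The per-pair orthogonalization
    and per-outcome inner products run in a compiled kernel whose sequential
    accumulation order is independent of partitioning and worker scheduling,
    so results are bit-identical across chunked and parallel runs.
    """
    from ._kernels import _outer_column_sweep

    p_in = Ic.shape[1]
    p_y = Yc.shape[1]
    tiny = np.finfo(float).tiny

    hits = []
    degenerate_pairs = 0
    skipped_outcomes = 0

    r = np.zeros((p_y, p_in))
    ok = np.zeros((p_y, p_in), dtype=np.bool_)
    for j in outer_idx:
        sso = ss_o[j]
        if sso <= tol * max(raw_ss_o[j], tiny):
            degenerate_pairs += p_in
            continue
        q2 = np.ascontiguousarray(Oc[:, j]) / math.sqrt(sso)

        r[:] = 0.0
        ok[:] = False
        deg, sk = _outer_column_sweep(
            np.ascontiguousarray(O_raw[:, j]), q2, I_raw, Ic, ss_i, raw_ss_i,
            Yc, ss_y, tol, r, ok,
        )
        degenerate_pairs += deg
        skipped_outcomes += sk
        if not ok.any():
            continue

        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / (1.0 - r * r))
            t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        np.minimum(p, 1.0, out=p)

        emit = ok & (p <= threshold)
        if emit.any():
            yi, ii = np.nonzero(emit)
            hits.append((j, yi.copy(), ii.copy(), r[yi, ii].copy(),
                         t[yi, ii], p[yi, ii]))

    return hits, degenerate_pairs, skipped_outcomes


def screen_triples(
    X: NamedMatrix,
    Y: NamedMatrix,
    Z: NamedMatrix,
    cfg: Optional[ScreenConfig] = None,
    outer_over: Optional[str] = None,
) -> ScreenResult:
    """Test the interaction coefficient for every (x, y, z) column triple.

    One candidate model is considered per triple — p1*p2*p3 in total — and the
    records with p <= cfg.p_threshold are returned sorted by (x column index,
    z column index, y column index).  Degenerate pairs (collinear designs) and
    outcomes lying in the design span are skipped and counted, never fitted.
    Results are identical for any worker count: work is partitioned over the
    larger of X/Z's column sets, and each pair's arithmetic is independent.

    ``outer_over`` ("x" or "z") pins the internal loop orientation; the
    chunked file driver uses it so every chunk computes with the orientation
    the whole-matrix run would choose, making partitioned runs bit-identical
    to unpartitioned ones.
    """
    if cfg is None:
        cfg = ScreenConfig()

    n = X.n_rows
    for name, M in (("Y", Y), ("Z", Z)):
        if M.n_rows != n:
            raise InputError(
                f"row count mismatch: X has {n} rows but {name} has {M.n_rows}"
            )
        if M.row_ids != X.row_ids:
            raise InputError(f"row ID order mismatch between X and {name}")
    if n <= 4:
        raise InputError(f"need at least 5 observations, got {n}")
    df = n - 4

    Xc, _, ssx = center_columns(X)
    Zc, _, ssz = center_columns(Z)
    Yc, _, ssy = center_columns(Y)
    raw_ssx = _column_sumsq(X.values)
    raw_ssz = _column_sumsq(Z.values)

    # outer loop over the matrix with more columns (better load balance);
    # the partial correlation is symmetric in x and z, so this only
    # reorders the computation, never the results
    if outer_over is None:
        swap = Z.n_cols > X.n_cols
    elif outer_over in ("x", "z"):
        swap = outer_over == "z"
    else:
        raise InputError(f"outer_over must be 'x' or 'z', got {outer_over!r}")
    if swap:
        O_raw, Oc, ss_o, raw_o = Z.values, Zc, ssz, raw_ssz
        I_raw, Ic, ss_i, raw_i = X.values, Xc, ssx, raw_ssx
    else:
        O_raw, Oc, ss_o, raw_o = X.values, Xc, ssx, raw_ssx
        I_raw, Ic, ss_i, raw_i = Z.values, Zc, ssz, raw_ssz

    p_outer = Oc.shape[1]
    n_workers = min(cfg.n_workers, max(p_outer, 1))
    blocks = np.array_split(np.arange(p_outer), n_workers)
    blocks = [b for b in blocks if b.size]

    run = delayed(_screen_outer_block)
    args = (O_raw, Oc, ss_o, raw_o, I_raw, Ic, ss_i, raw_i, Yc, ssy, df,
            cfg.p_threshold, cfg.degeneracy_tol)
    if n_workers == 1 or len(blocks) == 1:
        outputs = [_screen_outer_block(blocks[0], *args)] if blocks else []
    else:
        outputs = Parallel(n_jobs=len(blocks), prefer="threads")(
            run(b, *args) for b in blocks
        )

    records: list[ScreenRecord] = []
    degenerate_pairs = 0
    skipped_outcomes = 0
    for hits, deg, sk in outputs:
        degenerate_pairs += deg
        skipped_outcomes += sk
        for j, yi, ii, rv, tv, pv in hits:
            xi_arr, zi_arr = (ii, np.full_like(ii, j)) if swap else (np.full_like(ii, j), ii)
            for k in range(len(yi)):
                xi, zi = int(xi_arr[k]), int(zi_arr[k])
                records.append(
                    ScreenRecord(
                        x_name=X.col_names[xi],
                        y_name=Y.col_names[int(yi[k])],
                        z_name=Z.col_names[zi],
                        r=float(rv[k]),
                        t=float(tv[k]),
                        df=df,
                        p=float(pv[k]),
                        x_index=xi,
                        y_index=int(yi[k]),
                        z_index=zi,
                    )
                )

    records.sort(key=lambda rec: (rec.x_index, rec.z_index, rec.y_index))
    return ScreenResult(
        records=records,
        n_candidates=X.n_cols * Y.n_cols * Z.n_cols,
        degenerate_pairs=degenerate_pairs,
        skipped_outcomes=skipped_outcomes,
    )
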