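"""Input validation, alignment, and column-mean imputation.

All numerics downstream assume fully finite, row-aligned matrices; this module
is the single gate that enforces that.  Missing cells are replaced by the mean
of the non-missing values in their column, so the number of observations (and
hence the residual degrees of freedom n - 4) always equals the full row count.
Matrices must arrive with identical row-ID order: automatic reordering is
refused because it is a classic source of silent sample mix-ups in omics
screens — ``align`` reorders explicitly on request instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import InputError, NamedMatrix

__all__ = ["ValidationReport", "impute_column_means", "validate_triple", "align"]


@dataclass
class ValidationReport:
    """Outcome of validating an aligned (X, Y, Z) triple."""

    n_rows: int
    n_cols: dict[str, int]
    imputed_cells: dict[str, int] = field(default_factory=dict)
    flagged_columns: list[tuple[str, str, str]] = field(default_factory=list)
    # each flag: (matrix label, column name, reason)

    @property
    def n_flags(self) -> int:
        return len(self.flagged_columns)


def impute_column_means(
    values: np.ndarray,
    row_ids: list[str],
    col_names: list[str],
) -> tuple[NamedMatrix, int]:
    """Replace missing cells by the mean of their column's non-missing values.

    Returns the imputed matrix and the number of cells filled.  A column with
    no observed value at all cannot be imputed and is an input error.  The
    operation is idempotent and leaves each column's mean unchanged.
    """
    values = np.asarray(values, dtype=np.float64)
    missing = ~np.isfinite(values)
    n_missing_per_col = missing.sum(axis=0)
    empty = n_missing_per_col == values.shape[0]
    if empty.any():
        bad = [col_names[j] for j in np.nonzero(empty)[0]]
        raise InputError(
            "column(s) with no observed values cannot be imputed: " + ", ".join(bad)
        )
    if missing.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_means = np.nanmean(np.where(missing, np.nan, values), axis=0)
        values = np.where(missing, col_means[None, :], values)
    if len(set(col_names)) != len(col_names):
        warnings.warn(
            "duplicate column names present; records are tracked by index internally",
            stacklevel=2,
        )
    return NamedMatrix(values, list(row_ids), list(col_names)), int(missing.sum())


def validate_triple(X: NamedMatrix, Y: NamedMatrix, Z: NamedMatrix) -> ValidationReport:
    """Check that X, Y, Z are mutually consistent and screenable.

    Confirms equal row counts, identical row-ID order and n >= 5, and flags
    zero-variance columns (which the screen will skip as degenerate).
    """
    n = X.n_rows
    for label, M in (("Y", Y), ("Z", Z)):
        if M.n_rows != n:
            raise InputError(
                f"row count mismatch: X has {n} rows, {label} has {M.n_rows}"
            )
    for label, M in (("Y", Y), ("Z", Z)):
        if M.row_ids != X.row_ids:
            if sorted(M.row_ids) == sorted(X.row_ids):
                raise InputError(
                    f"row order mismatch between X and {label}: same IDs, different "
                    "order (reordering is not attempted; use align())"
                )
            raise InputError(f"row ID mismatch between X and {label}")
    if n <= 4:
        raise InputError(f"need at least 5 observations (n - 4 >= 1), got {n}")

    report = ValidationReport(
        n_rows=n,
        n_cols={"X": X.n_cols, "Y": Y.n_cols, "Z": Z.n_cols},
    )
    for label, M in (("X", X), ("Y", Y), ("Z", Z)):
        var = M.values.var(axis=0)
        for j in np.nonzero(var == 0.0)[0]:
            report.flagged_columns.append(
                (label, M.col_names[int(j)], "zero variance; will be skipped")
            )
    return report


def align(M: NamedMatrix, row_ids: list[str]) -> NamedMatrix:
    """Explicitly reorder a matrix's rows to match a reference row-ID order."""
    index = {rid: i for i, rid in enumerate(M.row_ids)}
    missing = [rid for rid in row_ids if rid not in index]
    if missing:
        raise InputError(f"row IDs absent from matrix: {missing[:5]}")
    if len(row_ids) != len(M.row_ids):
        raise InputError("reference row-ID list has a different length")
    order = [index[rid] for rid in row_ids]
    return NamedMatrix(M.values[order], list(row_ids), list(M.col_names))
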