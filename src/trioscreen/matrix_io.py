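"""Delimited-matrix I/O and the chunked multi-file screen driver.

Matrices are plain TSV/CSV: a header row of variable names, a leading
observation-ID column, numeric cells.  Missing values may be written as an
empty field, ``NA``, ``NaN`` or ``nan`` (case-insensitive).  For datasets too
large for memory, each matrix may be supplied as a list of column-partition
files; ``screen_files`` iterates over the Cartesian product of file triples,
loading one triple at a time, so peak memory is bounded by the largest single
triple while the merged results are identical to a whole-matrix run.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    InputError,
    NamedMatrix,
    ScreenConfig,
    ScreenRecord,
    ScreenResult,
    screen_triples,
)
from .preprocess import impute_column_means

__all__ = [
    "MatrixFileSpec",
    "read_matrix",
    "load_matrix",
    "write_matrix",
    "write_results",
    "read_results",
    "screen_files",
]

logger = logging.getLogger(__name__)

# accepted missing-value tokens, compared case-insensitively after stripping
MISSING_TOKENS = ("", "na", "nan")


@dataclass
class MatrixFileSpec:
    """Location and dialect of one matrix file.

    delimiter: "\\t" or ","; sniffed from the header line when None.
    orientation: "rows" when observations are rows (the default layout);
    "columns" transposes on load.
    """

    path: str
    delimiter: Optional[str] = None
    orientation: str = "rows"

    def __post_init__(self) -> None:
        if self.orientation not in ("rows", "columns"):
            raise InputError("orientation must be 'rows' or 'columns'")


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_matrix(spec: MatrixFileSpec | str) -> tuple[np.ndarray, list[str], list[str]]:
    """Parse a delimited matrix file into (values, row_ids, col_names).

    Missing tokens become NaN (imputation happens later, in preprocess).
    An unparseable cell is reported with its row ID and column name; ragged
    rows are an error.
    """
    if isinstance(spec, str):
        spec = MatrixFileSpec(spec)
    if not os.path.exists(spec.path):
        raise InputError(f"matrix file not found: {spec.path}")
    sep = spec.delimiter or _sniff_delimiter(spec.path)
    try:
        df = pd.read_csv(spec.path, sep=sep, index_col=0, dtype=str,
                         keep_default_na=False, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise InputError(f"cannot parse {spec.path}: {exc}") from exc
    if df.index.isna().any():
        raise InputError(f"{spec.path}: missing row ID")

    str_vals = np.char.strip(df.to_numpy(dtype=object).astype(str))
    lowered = np.char.lower(str_vals)
    missing = np.isin(lowered, MISSING_TOKENS)
    cleaned = np.where(missing, "nan", str_vals)
    try:
        # numpy's strtod path is correctly rounded, so a 17-significant-digit
        # text round trip reproduces doubles exactly
        numeric = cleaned.astype(np.float64)
    except ValueError:
        for (i, j), cell in np.ndenumerate(cleaned):
            try:
                float(cell)
            except ValueError:
                raise InputError(
                    f"{spec.path}: unparseable cell at row '{df.index[i]}', "
                    f"column '{df.columns[j]}': {str_vals[i, j]!r}"
                ) from None
        raise
    numeric[missing] = np.nan

    row_ids = [str(r) for r in df.index]
    col_names = [str(c) for c in df.columns]
    if spec.orientation == "columns":
        numeric = numeric.T
        row_ids, col_names = col_names, row_ids
    logger.info("read %s: %d rows x %d columns", spec.path, *numeric.shape)
    return numeric, row_ids, col_names


def load_matrix(spec: MatrixFileSpec | str) -> tuple[NamedMatrix, int]:
    """Read a matrix file and impute missing cells by column means."""
    values, row_ids, col_names = read_matrix(spec)
    return impute_column_means(values, row_ids, col_names)


def write_matrix(M: NamedMatrix, path: str, delimiter: str = "\t",
                 id_label: str = "id") -> None:
    """Write a matrix as delimited text with header and row-ID column."""
    df = pd.DataFrame(M.values, index=M.row_ids, columns=M.col_names)
    df.index.name = id_label
    df.to_csv(path, sep=delimiter, float_format="%.17g", na_rep="NA")


_RESULT_COLS = ["x_name", "y_name", "z_name", "pvalue"]
_STAT_COLS = ["r", "t", "df"]


def write_results(records: Sequence[ScreenRecord], path: str,
                  emit_statistics: bool = True) -> None:
    """Write screening records as a TSV table (canonically sorted input).

    p-values (and statistics) are serialized with 17 significant digits so a
    round-trip through text is exact in double precision.
    """
    cols = _RESULT_COLS + (_STAT_COLS if emit_statistics else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            row = [rec.x_name, rec.y_name, rec.z_name, f"{rec.p:.17g}"]
            if emit_statistics:
                row += [f"{rec.r:.17g}", f"{rec.t:.17g}", str(rec.df)]
            fh.write("\t".join(row) + "\n")


def read_results(path: str) -> list[ScreenRecord]:
    """Read a results TSV back into records (statistics optional)."""
    df = pd.read_csv(path, sep="\t", dtype={"x_name": str, "y_name": str, "z_name": str},
                     float_precision="round_trip")
    has_stats = all(c in df.columns for c in _STAT_COLS)
    records = []
    for _, row in df.iterrows():
        records.append(
            ScreenRecord(
                x_name=str(row["x_name"]),
                y_name=str(row["y_name"]),
                z_name=str(row["z_name"]),
                r=float(row["r"]) if has_stats else float("nan"),
                t=float(row["t"]) if has_stats else float("nan"),
                df=int(row["df"]) if has_stats else -1,
                p=float(row["pvalue"]),
            )
        )
    return records


def _as_specs(files: Sequence[MatrixFileSpec | str]) -> list[MatrixFileSpec]:
    return [f if isinstance(f, MatrixFileSpec) else MatrixFileSpec(f) for f in files]


def screen_files(
    x_files: Sequence[MatrixFileSpec | str],
    y_files: Sequence[MatrixFileSpec | str],
    z_files: Sequence[MatrixFileSpec | str],
    cfg: Optional[ScreenConfig] = None,
) -> ScreenResult:
    """Run the screen over column-partitioned matrix files, one triple at a time.

    Every file must carry identical row IDs in identical order.  Results are
    merged and sorted by (x file, x column, z file, z column, y file,
    y column) — identical to screening the concatenated matrices.  When
    ``cfg.output_path`` is set, per-triple partial results are appended to
    ``<output>.part`` as the run progresses (so a crash preserves work), and
    the merged sorted table replaces it at the end.
    """
    if cfg is None:
        cfg = ScreenConfig()
    x_specs, y_specs, z_specs = _as_specs(x_files), _as_specs(y_files), _as_specs(z_files)
    if not (x_specs and y_specs and z_specs):
        raise InputError("each of X, Y, Z needs at least one matrix file")

    # one pass over headers to pin row IDs and total column counts, so every
    # chunk computes with the orientation the whole-matrix run would use
    ref_ids: Optional[list[str]] = None
    ref_path = ""
    totals = {}
    for label, specs in (("X", x_specs), ("Y", y_specs), ("Z", z_specs)):
        count = 0
        for spec in specs:
            values, row_ids, col_names = read_matrix(spec)
            count += len(col_names)
            if ref_ids is None:
                ref_ids, ref_path = row_ids, spec.path
            elif row_ids != ref_ids:
                raise InputError(
                    f"row IDs in {spec.path} do not match {ref_path} "
                    "(same order is required)"
                )
        totals[label] = count
    orientation = "z" if totals["Z"] > totals["X"] else "x"

    part_path = cfg.output_path + ".part" if cfg.output_path else None
    if part_path and os.path.exists(part_path):
        os.remove(part_path)

    keyed: list[tuple[tuple, ScreenRecord]] = []
    n_candidates = 0
    degenerate_pairs = 0
    skipped_outcomes = 0
    for fx, x_spec in enumerate(x_specs):
        X, _ = load_matrix(x_spec)
        for fz, z_spec in enumerate(z_specs):
            Z, _ = load_matrix(z_spec)
            for fy, y_spec in enumerate(y_specs):
                Y, _ = load_matrix(y_spec)
                res = screen_triples(X, Y, Z, cfg, outer_over=orientation)
                n_candidates += res.n_candidates
                degenerate_pairs += res.degenerate_pairs
                skipped_outcomes += res.skipped_outcomes
                for rec in res.records:
                    keyed.append(
                        ((fx, rec.x_index, fz, rec.z_index, fy, rec.y_index), rec)
                    )
                logger.info(
                    "chunk X=%s Z=%s Y=%s: %d candidates, %d records",
                    x_spec.path, z_spec.path, y_spec.path,
                    res.n_candidates, len(res.records),
                )
                if part_path:
                    with open(part_path, "a") as fh:
                        for rec in res.records:
                            fh.write(
                                f"{rec.x_name}\t{rec.y_name}\t{rec.z_name}\t"
                                f"{rec.p:.17g}\n"
                            )

    keyed.sort(key=lambda kr: kr[0])
    records = [rec for _, rec in keyed]
    if cfg.output_path:
        write_results(records, cfg.output_path, cfg.emit_statistics)
        if part_path and os.path.exists(part_path):
            os.remove(part_path)
    return ScreenResult(
        records=records,
        n_candidates=n_candidates,
        degenerate_pairs=degenerate_pairs,
        skipped_outcomes=skipped_outcomes,
    )
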