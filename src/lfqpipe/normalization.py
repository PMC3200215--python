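"""Log2 transformation and quantile normalization of intensity matrices.

Matrices are pandas DataFrames (rows = aligned peptide features, columns =
injections) carrying a scale tag in ``df.attrs["scale"]`` that may only
progress raw -> log2 -> log2-quantile-normalized.

Quantile normalization forces every injection's intensity distribution onto
the common reference distribution (the across-column mean of each rank),
removing location/scale/shape differences introduced by sample handling and
instrument drift.  Ties within a column receive the mean of the reference
values at the tied ranks.  Missing cells are excluded from ranking; a
column with missing cells has its empirical quantiles interpolated onto the
reference distribution built from complete rows, which preserves the
same-distribution contract without imputing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataValidationError

RAW = "raw"
LOG2 = "log2"
NORMALIZED = "log2-quantile-normalized"


def _require_scale(m: pd.DataFrame, expected: str) -> None:
    scale = m.attrs.get("scale", RAW)
    if scale != expected:
        raise DataValidationError(
            f"matrix has scale {scale!r}; expected {expected!r} "
            "(allowed transitions: raw -> log2 -> log2-quantile-normalized)"
        )


def log2_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Cellwise log2; missing cells stay missing; nonpositive cells error."""
    _require_scale(m, RAW)
    values = m.to_numpy(dtype=float)
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        rows = list(m.index[bad.any(axis=1)])
        raise DataValidationError(
            f"nonpositive intensities cannot be log-transformed; rows: {rows[:10]}"
        )
    out = pd.DataFrame(np.log2(values), index=m.index, columns=m.columns)
    out.attrs["scale"] = LOG2
    return out


def _tied_group_means(col_sorted_vals: np.ndarray,
                      ref: np.ndarray, n_ref: int) -> np.ndarray:
    """Map ordered column values onto ref, averaging over tied ranks."""
    n = len(col_sorted_vals)
    if n == 1:
        grid = np.array([0.5 * (n_ref - 1)])
    else:
        grid = np.linspace(0.0, n_ref - 1, n)
    mapped = np.interp(grid, np.arange(n_ref), ref)
    # average mapped values over runs of equal input values (deterministic ties)
    out = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and col_sorted_vals[j + 1] == col_sorted_vals[i]:
            j += 1
        out[i : j + 1] = mapped[i : j + 1].mean()
        i = j + 1
    return out


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a log2 matrix across its columns.

    Each column is sorted, each rank replaced by the across-column mean of
    that rank (computed over complete rows when the matrix has missing
    cells), and the original order restored.  A single-column matrix is
    returned unchanged with a warning, since there is nothing to normalize
    against.
    """
    _require_scale(m, LOG2)
    if m.shape[1] == 0 or m.shape[0] == 0:
        raise DataValidationError("cannot normalize an empty matrix")
    if m.shape[1] == 1:
        warnings.warn("single-column matrix: quantile normalization is a no-op")
        out = m.copy()
        out.attrs["scale"] = NORMALIZED
        return out

    values = m.to_numpy(dtype=float)
    has_missing = np.isnan(values).any()
    if has_missing:
        complete = ~np.isnan(values).any(axis=1)
        if not complete.any():
            raise DataValidationError(
                "no complete rows available to build the reference distribution"
            )
        ref = np.sort(values[complete], axis=0).mean(axis=1)
    else:
        ref = np.sort(values, axis=0).mean(axis=1)
    n_ref = len(ref)

    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        present = ~np.isnan(col)
        if not present.any():
            continue
        idx = np.where(present)[0]
        order = np.argsort(col[idx], kind="stable")
        sorted_vals = col[idx][order]
        mapped = _tied_group_means(sorted_vals, ref, n_ref)
        out[idx[order], j] = mapped
    result = pd.DataFrame(out, index=m.index, columns=m.columns)
    result.attrs["scale"] = NORMALIZED
    return result


def check_normalized(m: pd.DataFrame, tol: float = 1e-9) -> tuple[bool, float]:
    """Verify all columns share one distribution; return (ok, discrepancy).

    Columns of equal length are compared by their sorted vectors; with
    missing cells, each column's quantile function is evaluated on a common
    grid.  The discrepancy is the largest absolute difference found.
    """
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise DataValidationError("cannot check an empty matrix")
    cols = []
    for j in range(m.shape[1]):
        col = m.iloc[:, j].dropna().to_numpy(dtype=float)
        if col.size == 0:
            raise DataValidationError(f"column {m.columns[j]!r} is entirely missing")
        cols.append(np.sort(col))
    lengths = {len(c) for c in cols}
    if len(lengths) == 1:
        stacked = np.vstack(cols)
    else:
        grid = np.linspace(0.0, 1.0, max(lengths))
        stacked = np.vstack(
            [np.interp(grid, np.linspace(0.0, 1.0, len(c)), c) for c in cols]
        )
    discrepancy = float((stacked.max(axis=0) - stacked.min(axis=0)).max())
    return discrepancy <= tol, discrepancy


def peptide_table_to_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long peptide table into a (protein, peptide) x injection matrix.

    Injection columns are ``sample::replicate``.  The result carries the raw
    scale tag; absent (protein, peptide, injection) combinations are missing.
    """
    required = {"protein", "peptide", "sample", "replicate", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise DataValidationError(f"peptide table lacks columns {sorted(missing)}")
    t = table.copy()
    t["injection"] = (
        t["sample"].astype(str) + "::" + t["replicate"].astype(int).astype(str)
    )
    wide = t.pivot_table(
        index=["protein", "peptide"],
        columns="injection",
        values="intensity",
        aggfunc="mean",
    )
    wide.attrs["scale"] = RAW
    return wide


def injection_design(table: pd.DataFrame) -> pd.DataFrame:
    """Extract the injection -> (sample, group, replicate) map from a table."""
    t = table.copy()
    t["injection"] = (
        t["sample"].astype(str) + "::" + t["replicate"].astype(int).astype(str)
    )
    design = (
        t[["injection", "sample", "group", "replicate"]]
        .drop_duplicates("injection")
        .set_index("injection")
        .sort_index()
    )
    return design
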