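"""Streaming statistics and subsetting of Matrix Market files.

Both operations iterate over the triplet lines of a coordinate-format
``.mtx`` file (one non-zero element per line) and keep only per-axis
accumulators, so peak additional memory scales with the axis lengths,
never with the number of non-zero entries.

Means and variances include the implicit zeros of the matrix; the
variance uses the population denominator (full axis length).
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .intervals import open_text


class MtxFormatError(ValueError):
    pass


def _read_header(fh: IO[str], path) -> tuple[int, int, int, str]:
    """Parse the banner + dimension line; returns (nrows, ncols, nnz, field)."""
    banner = fh.readline()
    if not banner.startswith("%%MatrixMarket"):
        raise MtxFormatError(f"{path}: missing MatrixMarket banner")
    parts = banner.strip().split()
    if len(parts) < 5 or parts[1] != "matrix" or parts[2] != "coordinate":
        raise MtxFormatError(f"{path}: only coordinate matrices are supported")
    field = parts[3]
    if field not in ("integer", "real"):
        raise MtxFormatError(f"{path}: unsupported field {field!r}")
    if parts[4] != "general":
        raise MtxFormatError(f"{path}: only 'general' symmetry is supported")
    line = fh.readline()
    while line.startswith("%"):
        line = fh.readline()
    try:
        nrows, ncols, nnz = (int(x) for x in line.split())
    except ValueError:
        raise MtxFormatError(f"{path}: malformed dimension line {line!r}") from None
    return nrows, ncols, nnz, field


def _finalize(
    nnz: np.ndarray,
    total: np.ndarray,
    sumsq: np.ndarray,
    mn: np.ndarray,
    mx: np.ndarray,
    axis_len: int,
    other_len: int,
) -> pd.DataFrame:
    """Fold implicit zeros into the accumulated per-index statistics."""
    n = float(other_len)
    mean = total / n if n else np.zeros(axis_len)
    var = np.maximum(sumsq / n - mean**2, 0.0) if n else np.zeros(axis_len)
    has_zero = nnz < other_len
    mn_out = np.where(nnz == 0, 0.0, mn)
    mx_out = np.where(nnz == 0, 0.0, mx)
    mn_out = np.where(has_zero, np.minimum(mn_out, 0.0), mn_out)
    mx_out = np.where(has_zero, np.maximum(mx_out, 0.0), mx_out)
    return pd.DataFrame(
        {
            "nonzero_count": nnz.astype(int),
            "sum": total,
            "mean": mean,
            "variance": var,
            "sd": np.sqrt(var),
            "min": mn_out,
            "max": mx_out,
        },
        index=pd.RangeIndex(1, axis_len + 1, name="index"),
    )


def mtx_stats(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-pass per-row and per-column statistics of an MTX file.

    Returns ``(row_stats, col_stats)`` DataFrames (1-based index) with
    columns nonzero_count, sum, mean, variance, sd, min, max.  Implicit
    zeros are included in mean/variance/min/max.
    """
    with open_text(path) as fh:
        nrows, ncols, _, _ = _read_header(fh, path)
        r_nnz = np.zeros(nrows, dtype=np.int64)
        r_sum = np.zeros(nrows)
        r_sq = np.zeros(nrows)
        r_min = np.full(nrows, np.inf)
        r_max = np.full(nrows, -np.inf)
        c_nnz = np.zeros(ncols, dtype=np.int64)
        c_sum = np.zeros(ncols)
        c_sq = np.zeros(ncols)
        c_min = np.full(ncols, np.inf)
        c_max = np.full(ncols, -np.inf)
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            v = float(parts[2])
            if not (0 <= i < nrows and 0 <= j < ncols):
                raise MtxFormatError(
                    f"{path}: entry ({i + 1}, {j + 1}) outside declared {nrows}x{ncols}"
                )
            r_nnz[i] += 1
            r_sum[i] += v
            r_sq[i] += v * v
            r_min[i] = min(r_min[i], v)
            r_max[i] = max(r_max[i], v)
            c_nnz[j] += 1
            c_sum[j] += v
            c_sq[j] += v * v
            c_min[j] = min(c_min[j], v)
            c_max[j] = max(c_max[j], v)
    rows = _finalize(r_nnz, r_sum, r_sq, r_min, r_max, nrows, ncols)
    cols = _finalize(c_nnz, c_sum, c_sq, c_min, c_max, ncols, nrows)
    return rows, cols


def mtx_subset(
    path,
    out_path,
    keep_rows: Sequence[int] | None = None,
    keep_cols: Sequence[int] | None = None,
) -> None:
    """Stream-subset an MTX file to the given 1-based row/column indices.

    Kept triplets are reindexed to dense 1..k order following the order
    of the keep lists; the input's triplet ordering is preserved (no
    re-sorting).  ``None`` keeps the whole axis.
    """
    out_path = Path(out_path)
    with open_text(path) as fh:
        nrows, ncols, _, field = _read_header(fh, path)
        if keep_rows is None:
            keep_rows = range(1, nrows + 1)
        if keep_cols is None:
            keep_cols = range(1, ncols + 1)
        for idx, n, axis in ((keep_rows, nrows, "row"), (keep_cols, ncols, "column")):
            for i in idx:
                if not (1 <= i <= n):
                    raise IndexError(f"{axis} index {i} outside 1..{n}")
        row_map = {old: new for new, old in enumerate(keep_rows, start=1)}
        col_map = {old: new for new, old in enumerate(keep_cols, start=1)}
        kept = 0
        with tempfile.NamedTemporaryFile(
            "w+t", dir=out_path.parent, delete=False, suffix=".triplets"
        ) as tmp:
            tmp_path = Path(tmp.name)
            for line in fh:
                if not line.strip():
                    continue
                parts = line.split()
                ri = row_map.get(int(parts[0]))
                ci = col_map.get(int(parts[1]))
                if ri is None or ci is None:
                    continue
                tmp.write(f"{ri} {ci} {parts[2]}\n")
                kept += 1
    with open(out_path, "wt") as out:
        out.write(f"%%MatrixMarket matrix coordinate {field} general\n")
        out.write(f"{len(row_map)} {len(col_map)} {kept}\n")
        with open(tmp_path, "rt") as tmp_in:
            for line in tmp_in:
                out.write(line)
    tmp_path.unlink()
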