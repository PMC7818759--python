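"""Whitespace-delimited ASCII matrix files and region-label tables.

The connectivity supplements of resting-state studies are commonly shipped as
plain text: one matrix row per line, columns separated by spaces or tabs, no
header.  Readers here are strict about shape and numeric content so that a
malformed file fails loudly with the offending line number.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = ["MatrixFormatError", "read_matrix", "write_matrix", "read_region_labels"]


class MatrixFormatError(ValueError):
    """Raised when an ASCII matrix file is ragged or non-numeric."""


def read_matrix(path: str | os.PathLike) -> np.ndarray:
    """Read a whitespace-delimited ASCII matrix.

    Blank lines are ignored.  Raises :class:`MatrixFormatError` naming the
    line for ragged rows or non-numeric tokens.
    """
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                row = [float(tok) for tok in tokens]
            except ValueError as exc:
                raise MatrixFormatError(
                    f"{path}: non-numeric token on line {lineno}: {exc}"
                ) from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise MatrixFormatError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(row)} columns, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise MatrixFormatError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def write_matrix(path: str | os.PathLike, matrix: np.ndarray) -> None:
    """Write a 2-D array as whitespace-delimited ASCII, one row per line.

    Values are printed with 17 significant digits so a read/write round trip
    is lossless at double precision.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got ndim={matrix.ndim}")
    np.savetxt(path, matrix, fmt="%.17g", delimiter=" ")


def read_region_labels(path: str | os.PathLike) -> list[str]:
    """Read a region-label CSV with columns ``index`` (1-based) and ``label``."""
    table = pd.read_csv(path)
    missing = {"index", "label"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    table = table.sort_values("index")
    expected = np.arange(1, len(table) + 1)
    if not np.array_equal(table["index"].to_numpy(), expected):
        raise ValueError(f"{path}: region indices must be 1..{len(table)} without gaps")
    return table["label"].astype(str).tolist()
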