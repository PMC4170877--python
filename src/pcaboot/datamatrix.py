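"""Numeric object-by-variable matrices with standardization metadata.

The whole package operates on :class:`DataMatrix`: an ``n x p`` table of
``n`` objects (rows, e.g. one EEG recording per subject and condition) on
``p`` variables (columns, e.g. spectral band powers). PCA on a correlation
matrix requires column-standardized input; :func:`standardize` produces it
while remembering the original column means and standard deviations so that
supplementary observations can later be expressed on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DataMatrix", "standardize", "read_matrix_csv", "write_matrix_csv"]

_STD_TOL = 1e-10


@dataclass
class DataMatrix:
    """An n x p real matrix with row identifiers and column names.

    Parameters
    ----------
    values
        ``(n, p)`` float array, no missing values, ``n >= 3``, ``p >= 2``.
    row_ids, col_names
        Unique labels for rows and columns.
    standardized
        True if every column has mean 0 and sample SD 1 (n-1 denominator).
    col_means, col_sds
        Original-scale column moments. For a raw matrix these are simply its
        own moments; for a standardized matrix they are the moments of the
        source matrix that standardization divided out.
    """

    values: np.ndarray
    row_ids: list[str]
    col_names: list[str]
    standardized: bool = False
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 3:
            raise ValueError(f"need at least 3 rows, got {n}")
        if p < 2:
            raise ValueError(f"need at least 2 columns, got {p}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite values")
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_names = [str(c) for c in self.col_names]
        if len(self.row_ids) != n:
            raise ValueError("row_ids length does not match row count")
        if len(self.col_names) != p:
            raise ValueError("col_names length does not match column count")
        if self.standardized:
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0, ddof=1)
            if np.abs(mu).max() > _STD_TOL or np.abs(sd - 1.0).max() > _STD_TOL:
                raise ValueError(
                    "standardized flag set but columns are not mean-0 / SD-1"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "DataMatrix":
        return replace(
            self,
            values=self.values.copy(),
            row_ids=list(self.row_ids),
            col_names=list(self.col_names),
            col_means=None if self.col_means is None else self.col_means.copy(),
            col_sds=None if self.col_sds is None else self.col_sds.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_names)


def standardize(X: DataMatrix) -> DataMatrix:
    """Column-standardize a matrix (mean 0, sample SD 1, n-1 denominator).

    Idempotent: an already standardized matrix is returned as an unchanged
    copy. The source means/SDs are stored on the result so supplementary rows
    can be brought onto the same scale.

    Raises
    ------
    ValueError
        If any column is (numerically) constant, naming the column.
    """
    if X.standardized:
        return X.copy()
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        names = ", ".join(X.col_names[j] for j in bad)
        raise ValueError(f"cannot standardize constant column(s): {names}")
    vals = (X.values - mu) / sd
    return DataMatrix(
        values=vals,
        row_ids=list(X.row_ids),
        col_names=list(X.col_names),
        standardized=True,
        col_means=mu,
        col_sds=sd,
    )


def read_matrix_csv(path: str | Path) -> DataMatrix:
    """Read a matrix from CSV: first column row ids, header row variable names."""
    df = pd.read_csv(path, index_col=0)
    return DataMatrix(
        values=df.to_numpy(dtype=float),
        row_ids=[str(i) for i in df.index],
        col_names=[str(c) for c in df.columns],
    )


def write_matrix_csv(X: DataMatrix, path: str | Path) -> None:
    X.to_frame().to_csv(path, index_label="id")
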