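"""Numeric data matrix with labelled rows/columns and an explicit missing marker.

Rows are observations (time points or samples), columns are variables
(species, genes, metabolite concentrations, ...). Missing cells are carried
as NaN. This is the ``X`` that every curation and inference step operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["NumericMatrix", "autoscale"]


@dataclass
class NumericMatrix:
    """An n x p real matrix with unique row/column labels; NaN marks missing.

    Parameters
    ----------
    values : (n, p) float array. NaN cells are missing.
    row_ids : n unique labels (defaults to "r0", "r1", ...).
    column_ids : p unique labels (defaults to "v0", "v1", ...).
    """

    values: np.ndarray
    row_ids: list[str] = field(default=None)  # type: ignore[assignment]
    column_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if self.row_ids is None:
            self.row_ids = [f"r{i}" for i in range(n)]
        if self.column_ids is None:
            self.column_ids = [f"v{j}" for j in range(p)]
        self.row_ids = [str(r) for r in self.row_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        if len(self.row_ids) != n:
            raise ValueError(f"{len(self.row_ids)} row_ids for {n} rows")
        if len(self.column_ids) != p:
            raise ValueError(f"{len(self.column_ids)} column_ids for {p} columns")
        if len(set(self.row_ids)) != n:
            raise ValueError("row_ids must be unique")
        if len(set(self.column_ids)) != p:
            raise ValueError("column_ids must be unique")
        fully_missing = np.isnan(self.values).all(axis=0)
        if fully_missing.any():
            bad = [self.column_ids[j] for j in np.flatnonzero(fully_missing)]
            raise ValueError(f"columns entirely missing: {bad}")

    # -- basic queries -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, p) mask, True where the cell is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def copy(self) -> "NumericMatrix":
        return NumericMatrix(self.values.copy(), list(self.row_ids), list(self.column_ids))

    # -- conversions ---------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "NumericMatrix":
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns])

    def subset_rows(self, idx: Sequence[int]) -> "NumericMatrix":
        idx = list(idx)
        return NumericMatrix(self.values[idx], [self.row_ids[i] for i in idx], list(self.column_ids))


def autoscale(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center to zero mean and scale to unit (ddof=1) standard deviation.

    Returns (scaled, mean, std). Constant columns are rejected: unit-variance
    scaling is undefined for them.
    """
    values = np.asarray(values, dtype=float)
    mean = np.nanmean(values, axis=0)
    std = np.nanstd(values, axis=0, ddof=1)
    if np.any(std == 0) or np.any(~np.isfinite(std)):
        raise ValueError("autoscaling undefined: constant column present")
    return (values - mean) / std, mean, std
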