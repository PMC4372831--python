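"""Quantitative bipartite web container.

Orientation is fixed package-wide: rows are plants, columns are birds (so the
matrix is plants x birds everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd


@dataclass
class QuantitativeWeb:
    """Plants x birds matrix of non-negative interaction frequencies."""

    matrix: np.ndarray
    row_names: List[str] = field(default_factory=list)
    col_names: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("web matrix must be 2-dimensional")
        n_rows, n_cols = self.matrix.shape
        if not self.row_names:
            self.row_names = [f"plant_{i + 1}" for i in range(n_rows)]
        if not self.col_names:
            self.col_names = [f"bird_{j + 1}" for j in range(n_cols)]
        if len(self.row_names) != n_rows or len(self.col_names) != n_cols:
            raise ValueError("row/col name lengths do not match matrix shape")
        if np.any(self.matrix < 0):
            raise ValueError("web matrix has negative cells")

    @property
    def shape(self) -> tuple:
        return self.matrix.shape

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_names, columns=self.col_names)

    def write_csv(self, path: Union[str, Path]) -> None:
        """Write as CSV with plant row labels and bird column headers."""
        df = self.to_dataframe()
        df.index.name = "plant"
        df.to_csv(path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "QuantitativeWeb":
        return cls(df.to_numpy(dtype=float), list(map(str, df.index)), list(map(str, df.columns)))

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "QuantitativeWeb":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))
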