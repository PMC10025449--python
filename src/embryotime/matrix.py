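"""Typed containers for the count, normalized, and distance matrices.

All matrices are genes x embryos (genes on rows), mirroring how
single-embryo CEL-Seq2 count tables are distributed.  Containers are
thin wrappers over :class:`pandas.DataFrame` that validate their
invariants on construction and are treated as immutable by every
operation in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "NormalizedMatrix", "DistanceMatrix"]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} identifiers: {dupes}")


@dataclass(frozen=True)
class CountMatrix:
    """UMI-deduplicated counts, genes x embryos, non-negative integers."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("CountMatrix.values must be a DataFrame")
        _check_unique(v.index, "gene")
        _check_unique(v.columns, "embryo")
        arr = v.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValueError(
                    f"non-integer count at gene {v.index[bad[0]]!r}, "
                    f"embryo {v.columns[bad[1]]!r}"
                )
            object.__setattr__(self, "values", v.astype(np.int64))
            arr = self.values.to_numpy()
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {v.index[bad[0]]!r}, "
                f"embryo {v.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def embryo_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_embryos(self) -> int:
        return self.values.shape[1]

    def totals(self) -> pd.Series:
        """Per-embryo total UMI counts (library sizes)."""
        return self.values.sum(axis=0)


@dataclass(frozen=True)
class NormalizedMatrix:
    """Size-factor normalized counts; every embryo sums to ``target_total``."""

    values: pd.DataFrame
    size_factors: pd.Series
    target_total: float

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "embryo")
        if not (self.size_factors > 0).all():
            raise ValueError("size factors must be positive")
        if self.target_total <= 0:
            raise ValueError("target_total must be positive")
        sums = self.values.to_numpy().sum(axis=0)
        if self.values.shape[0] and not np.allclose(
            sums, self.target_total, rtol=1e-6
        ):
            raise ValueError("normalized column sums do not match target_total")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def embryo_ids(self) -> pd.Index:
        return self.values.columns

    def log_values(self) -> pd.DataFrame:
        """log2(x + 1) transform used for distances and trajectory geometry."""
        return np.log2(self.values + 1.0)


@dataclass(frozen=True)
class DistanceMatrix:
    """Between-embryo distances, 1 - Pearson correlation, in [0, 2]."""

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not v.index.equals(v.columns):
            raise ValueError("distance matrix must be square with matching ids")
        arr = v.to_numpy()
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if arr.size and (arr.min() < -1e-9 or arr.max() > 2 + 1e-9):
            raise ValueError("correlation distances must lie in [0, 2]")

    @property
    def embryo_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_embryos(self) -> int:
        return self.values.shape[0]
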