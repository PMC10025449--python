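"""Embryo and gene filtering, library-size normalization, and distances.

The QC chain runs embryos first, genes second: low-depth embryos are
removed before the gene detection filter is evaluated, so a gene's
"detected in >= min_embryos" count refers to embryos that survive QC.
Normalization is median-of-totals size-factor scaling; distances are
1 - Pearson correlation of log2(normalized + 1) profiles.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd

from .matrix import CountMatrix, DistanceMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 250_000
DEFAULT_MIN_COUNT = 3
DEFAULT_MIN_EMBRYOS = 5

__all__ = [
    "filter_embryos",
    "filter_genes",
    "normalize",
    "distance_matrix",
    "DEFAULT_MIN_TOTAL",
    "DEFAULT_MIN_COUNT",
    "DEFAULT_MIN_EMBRYOS",
]


def filter_embryos(
    m: CountMatrix, min_total: int = DEFAULT_MIN_TOTAL
) -> tuple[CountMatrix, list[str]]:
    """Drop embryos with total UMI count below ``min_total``.

    Returns the filtered matrix (column order preserved) and the list of
    removed embryo ids.
    """
    totals = m.totals()
    keep = totals >= min_total
    removed = list(totals.index[~keep])
    if not keep.any():
        raise ValueError(
            f"all {m.n_embryos} embryos fall below min_total={min_total}; "
            "review the depth threshold for this dataset"
        )
    if removed:
        logger.info("filter_embryos: removed %d of %d embryos", len(removed), m.n_embryos)
    return CountMatrix(m.values.loc[:, keep]), removed


def filter_genes(
    m: CountMatrix,
    min_count: int = DEFAULT_MIN_COUNT,
    min_embryos: int = DEFAULT_MIN_EMBRYOS,
) -> tuple[CountMatrix, list[str]]:
    """Keep genes with >= ``min_count`` counts in >= ``min_embryos`` embryos."""
    if min_embryos > m.n_embryos:
        raise ValueError(
            f"min_embryos={min_embryos} exceeds the {m.n_embryos} embryos present"
        )
    qualifying = (m.values >= min_count).sum(axis=1)
    keep = qualifying >= min_embryos
    removed = list(m.gene_ids[~keep])
    if removed:
        logger.info("filter_genes: removed %d of %d genes", len(removed), m.n_genes)
    return CountMatrix(m.values.loc[keep]), removed


def normalize(m: CountMatrix) -> NormalizedMatrix:
    """Median-of-totals size-factor normalization.

    size_factor_i = total_i / median(totals); after division every
    embryo's column sums to the median library size.
    """
    totals = m.totals().astype(float)
    if (totals <= 0).any():
        zero = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total embryos present (should be filtered): {zero}")
    target = float(np.median(totals.to_numpy()))
    size_factors = totals / target
    values = m.values / size_factors
    return NormalizedMatrix(values=values, size_factors=size_factors, target_total=target)


def distance_matrix(
    nm: NormalizedMatrix, log: bool = True, method: Literal["pearson", "spearman"] = "pearson"
) -> DistanceMatrix:
    """1 - correlation distance between embryo expression profiles.

    Profiles are log2(x+1)-transformed by default (``log=False`` computes
    correlations on the normalized values directly).  Pearson is the
    tested default; Spearman is available behind the flag.
    """
    if nm.values.shape[1] < 2:
        raise ValueError("need at least 2 embryos for a distance matrix")
    if nm.values.shape[0] < 2:
        raise ValueError("need at least 2 genes for a distance matrix")
    x = nm.log_values() if log else nm.values
    arr = x.to_numpy(dtype=float)
    if method == "spearman":
        from scipy.stats import rankdata

        arr = rankdata(arr, axis=0)
    sd = arr.std(axis=0)
    if (sd == 0).any():
        flat = list(nm.embryo_ids[sd == 0])
        raise ValueError(f"zero-variance expression profile for embryos: {flat}")
    corr = np.corrcoef(arr, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    df = pd.DataFrame(d, index=nm.embryo_ids, columns=nm.embryo_ids)
    return DistanceMatrix(df)
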