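"""Marker-set scoring along pseudo-time (minor/major zygotic waves)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import NormalizedMatrix
from .trajectory import PseudotimeOrder

logger = logging.getLogger(__name__)

__all__ = ["MarkerSet", "score_set", "local_trend"]


@dataclass(frozen=True)
class MarkerSet:
    """A named, curated gene set (e.g. minor- or major-wave genes)."""

    name: str
    genes: tuple[str, ...]
    expected_count: int | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"marker set {self.name!r} has duplicate gene ids")
        if self.expected_count is not None and len(self.genes) != self.expected_count:
            raise ValueError(
                f"marker set {self.name!r} has {len(self.genes)} genes, "
                f"expected {self.expected_count}"
            )

    @classmethod
    def from_file(cls, name: str, path) -> "MarkerSet":
        genes = tuple(
            line.strip() for line in open(path) if line.strip() and not line.startswith("#")
        )
        return cls(name=name, genes=genes)


def score_set(
    nm: NormalizedMatrix, order: PseudotimeOrder, marker_set: MarkerSet
) -> pd.DataFrame:
    """Combined log2 expression of a marker set per embryo, in rank order.

    The score is the sum over set genes of log2(normalized count + 1);
    genes missing from the matrix (e.g. removed by QC) are logged and
    skipped.  Returns (embryo_id, rank, score) sorted by rank.
    """
    present = [g for g in marker_set.genes if g in nm.gene_ids]
    if not present:
        raise ValueError(
            f"no genes of marker set {marker_set.name!r} present in the matrix"
        )
    absent = set(marker_set.genes) - set(present)
    if absent:
        logger.info(
            "score_set(%s): %d of %d genes absent after QC",
            marker_set.name,
            len(absent),
            len(marker_set.genes),
        )
    score = np.log2(nm.values.loc[present] + 1.0).sum(axis=0)
    out = pd.DataFrame(
        {"embryo_id": nm.embryo_ids, "rank": order.ranks[nm.embryo_ids], "score": score}
    )
    return out.sort_values("rank").set_index("embryo_id", drop=False)


def local_trend(scores: pd.DataFrame, bandwidth: float = 0.3) -> pd.DataFrame:
    """LOWESS trend of marker scores over pseudo-time rank.

    ``bandwidth`` is the fraction of embryos in each local fit.  Returns
    the input frame with a ``trend`` column appended.
    """
    if not 0.0 < bandwidth <= 1.0:
        raise ValueError("bandwidth must lie in (0, 1]")
    if len(scores) < 10:
        raise ValueError("need at least 10 embryos for a local trend")
    fitted = lowess(
        scores["score"].to_numpy(),
        scores["rank"].to_numpy(dtype=float),
        frac=bandwidth,
        return_sorted=False,
    )
    out = scores.copy()
    out["trend"] = fitted
    return out
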