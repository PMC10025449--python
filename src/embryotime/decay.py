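"""Maternal transcript definition, decay testing, and quartile kinetics.

Maternally deposited transcripts are defined operationally: genes whose
mean normalized count over the earliest pseudo-time embryos exceeds a
floor were present before zygotic transcription could contribute.
Decay is then quantified by NB differential expression between the
youngest cluster and the cluster at the onset of the major zygotic wave,
and the significantly degraded genes are split into abundance quartiles
to ask whether the decay rate depends on how much transcript the egg
started with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import Clustering
from .diffexp import DEResult, compare_clusters
from .matrix import NormalizedMatrix
from .trajectory import PseudotimeOrder

__all__ = [
    "DecayReport",
    "maternal_set",
    "decay_de",
    "quartile_decay",
    "class_overlap",
]


@dataclass(frozen=True)
class DecayReport:
    """Quartile-resolved decay summary.

    ``quartile`` maps each degraded gene to Q1..Q4 (Q1 = lowest initial
    abundance); ``cluster_means`` holds, per (cluster, quartile), the
    mean over embryos of the summed normalized counts of that
    quartile's genes; ``ratios`` is last-cluster / first-cluster per
    quartile.
    """

    maternal: list[str]
    degraded: pd.DataFrame  # gene_id, log2FC, padj
    quartile: pd.Series
    cluster_means: pd.DataFrame  # cluster x quartile
    ratios: pd.Series  # per quartile


def maternal_set(
    nm: NormalizedMatrix,
    order: PseudotimeOrder,
    n_first: int = 10,
    min_mean: float = 1.0,
) -> list[str]:
    """Genes averaging > ``min_mean`` normalized counts over the
    ``n_first`` earliest-ranked embryos."""
    ranks = order.ranks
    if n_first > len(ranks):
        raise ValueError(f"n_first={n_first} exceeds the {len(ranks)} ordered embryos")
    earliest = ranks.sort_values().index[:n_first]
    means = nm.values[list(earliest)].mean(axis=1)
    return list(means.index[means > min_mean])


def decay_de(
    nm: NormalizedMatrix,
    clustering: Clustering,
    first_cluster,
    last_cluster,
    maternal: list[str],
    padj_threshold: float = 0.01,
    lfc_threshold: float = -1.0,
) -> tuple[pd.DataFrame, DEResult]:
    """Significantly degraded maternal transcripts between two clusters.

    Returns the degraded-gene table (padj < threshold and
    log2FC < ``lfc_threshold``, i.e. lower in the later cluster) plus
    the full DE result over the maternal set.
    """
    if not maternal:
        raise ValueError("maternal gene set is empty")
    de = compare_clusters(
        nm,
        clustering,
        first_cluster,
        last_cluster,
        padj_threshold=padj_threshold,
        lfc_threshold=abs(lfc_threshold),
        genes=maternal,
    )
    t = de.table
    hit = (t["padj"] < padj_threshold) & (t["log2FC"] < lfc_threshold)
    degraded = t.loc[hit, ["gene_id", "log2FC", "padj"]].copy()
    return degraded, de


def quartile_decay(
    nm: NormalizedMatrix,
    clustering: Clustering,
    degraded: list[str],
    first_cluster,
    last_cluster,
    maternal: list[str] | None = None,
) -> DecayReport:
    """Quartile-resolved decay of the degraded transcripts.

    Quartiles are assigned by per-gene mean normalized abundance in
    ``first_cluster`` (ties broken by gene id); quartile sizes differ by
    at most one.  For each cluster the mean over its embryos of the
    summed normalized counts per quartile is reported, together with the
    last/first-cluster ratio per quartile.
    """
    if len(degraded) == 0:
        raise ValueError("degraded gene set is empty")
    first_members = clustering.members(first_cluster)
    base = nm.values.loc[degraded, first_members].mean(axis=1)
    ranked = base.reset_index()
    ranked.columns = ["gene_id", "mean"]
    ranked = ranked.sort_values(["mean", "gene_id"], kind="mergesort")
    parts = np.array_split(ranked["gene_id"].to_numpy(), 4)
    quartile = pd.Series(index=pd.Index(degraded, name="gene_id"), dtype=object)
    for qi, genes in enumerate(parts, start=1):
        quartile[genes] = f"Q{qi}"

    per_embryo = {}
    for q in ("Q1", "Q2", "Q3", "Q4"):
        genes = list(quartile.index[quartile == q])
        per_embryo[q] = nm.values.loc[genes].sum(axis=0)
    sums = pd.DataFrame(per_embryo)
    cluster_means = sums.groupby(clustering.labels).mean()
    cluster_means.index.name = "cluster"

    first_means = cluster_means.loc[first_cluster]
    if (first_means == 0).any():
        zero_q = list(first_means.index[first_means == 0])
        raise ValueError(f"zero first-cluster mean for quartile(s) {zero_q}")
    ratios = cluster_means.loc[last_cluster] / first_means
    ratios.name = "ratio_last_over_first"
    return DecayReport(
        maternal=list(maternal) if maternal is not None else list(degraded),
        degraded=pd.DataFrame({"gene_id": degraded}).set_index("gene_id", drop=False),
        quartile=quartile,
        cluster_means=cluster_means,
        ratios=ratios,
    )


def class_overlap(degraded: list[str], decay_classes: pd.Series) -> pd.DataFrame:
    """Share of degraded genes per previously reported degradation class.

    Genes absent from the class table are labelled "unknown".  Returns
    (class, n_genes, fraction); fractions sum to 1, empty input gives an
    empty frame.
    """
    if len(degraded) == 0:
        return pd.DataFrame(columns=["class", "n_genes", "fraction"])
    labels = [decay_classes.get(g, "unknown") for g in degraded]
    counts = pd.Series(labels).value_counts()
    return pd.DataFrame(
        {
            "class": counts.index,
            "n_genes": counts.to_numpy(),
            "fraction": counts.to_numpy() / len(degraded),
        }
    )
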