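"""Lineage tree, pseudo-time ordering, and unfertilized-egg calling.

The cluster medoids' log-expression profiles are joined by a minimum
spanning tree; each embryo receives a normalized projection coordinate
on a tree edge incident to its own cluster.  When the tree is a simple
path — the expected topology for a cohort spanning a single
developmental continuum — traversing it end to end orders all embryos.
The direction is anchored biologically: the path end whose embryos
express less of an early-zygotic marker set is called youngest.

Unfertilized eggs betray themselves by combining a high pseudo-time
position (maternal decay has progressed) with absent early-zygotic
transcription; embryos early in pseudo-time with silent markers are too
young to judge and stay indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .cluster import Clustering
from .matrix import NormalizedMatrix

__all__ = [
    "LineageTree",
    "PseudotimeOrder",
    "lineage_tree",
    "pseudotime",
    "call_fertilization",
    "crosstab_order_vs_window",
]


@dataclass(frozen=True)
class LineageTree:
    """MST over cluster medoid profiles plus per-embryo edge projections.

    ``assignment`` has one row per embryo: its cluster, the assigned
    edge (cluster pair ``edge_a`` -> ``edge_b``, with ``edge_a`` the
    embryo's own cluster) and the clamped projection coordinate ``s``
    in [0, 1] along that edge.
    """

    nodes: list[int]
    edges: list[tuple[int, int]]
    assignment: pd.DataFrame

    def degree(self, node: int) -> int:
        return sum(node in e for e in self.edges)


@dataclass(frozen=True)
class PseudotimeOrder:
    """Total order of embryos along the lineage path (rank 1 = youngest)."""

    order: pd.DataFrame  # embryo_id, rank, cluster, coord
    path: list[int]
    direction_anchor: str

    @property
    def ranks(self) -> pd.Series:
        return self.order.set_index("embryo_id")["rank"]

    def rank_percentile(self) -> pd.Series:
        n = len(self.order)
        return self.ranks / n


def _medoid_profiles(nm: NormalizedMatrix, c: Clustering) -> pd.DataFrame:
    logx = nm.log_values()
    return pd.DataFrame(
        {cl: logx[c.medoid_of(cl)] for cl in range(1, c.k + 1)}
    )


def lineage_tree(nm: NormalizedMatrix, c: Clustering) -> LineageTree:
    """Build the medoid MST and project every embryo onto an incident edge."""
    if c.k < 2:
        raise ValueError("lineage tree requires at least 2 clusters")
    med = _medoid_profiles(nm, c)  # genes x clusters
    clusters = list(med.columns)
    M = med.to_numpy().T  # clusters x genes
    diff = M[:, None, :] - M[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    mst = minimum_spanning_tree(D).toarray()
    edges = [
        (clusters[i], clusters[j])
        for i, j in zip(*np.nonzero(mst))
    ]
    edges = [tuple(sorted(e)) for e in edges]

    neighbors: dict[int, list[int]] = {cl: [] for cl in clusters}
    for a, b in edges:
        neighbors[a].append(b)
        neighbors[b].append(a)

    logx = nm.log_values()
    rows = []
    for emb in nm.embryo_ids:
        cl = int(c.labels[emb])
        x = logx[emb].to_numpy()
        ma = med[cl].to_numpy()
        best_s, best_nb = -np.inf, None
        for nb in sorted(neighbors[cl]):
            v = med[nb].to_numpy() - ma
            denom = float(v @ v)
            s = float((x - ma) @ v) / denom
            if s > best_s:
                best_s, best_nb = s, nb
        rows.append(
            {
                "embryo_id": emb,
                "cluster": cl,
                "edge_a": cl,
                "edge_b": best_nb,
                "s": float(np.clip(best_s, 0.0, 1.0)),
            }
        )
    assignment = pd.DataFrame(rows).set_index("embryo_id", drop=False)
    return LineageTree(nodes=clusters, edges=sorted(edges), assignment=assignment)


def _path_order(tree: LineageTree) -> list[int]:
    """Traverse the tree end to end; error if it is not a simple path."""
    degrees = {node: tree.degree(node) for node in tree.nodes}
    branched = [n for n, deg in degrees.items() if deg > 2]
    if branched:
        raise ValueError(
            f"lineage tree branches at cluster(s) {branched}; "
            "pseudo-time requires a single trajectory"
        )
    ends = [n for n, deg in degrees.items() if deg == 1]
    adjacency: dict[int, list[int]] = {n: [] for n in tree.nodes}
    for a, b in tree.edges:
        adjacency[a].append(b)
        adjacency[b].append(a)
    start = min(ends)
    path = [start]
    prev = None
    while True:
        nxt = [n for n in adjacency[path[-1]] if n != prev]
        if not nxt:
            break
        prev = path[-1]
        path.append(nxt[0])
    if len(path) != len(tree.nodes):
        raise ValueError("lineage tree is not a connected path")
    return path


def _marker_scores(nm: NormalizedMatrix, early_markers) -> pd.Series:
    markers = [g for g in early_markers if g in nm.gene_ids]
    if not markers:
        raise ValueError("none of the early marker genes are present in the matrix")
    return nm.values.loc[markers].sum(axis=0)


def pseudotime(
    tree: LineageTree, nm: NormalizedMatrix, early_markers
) -> PseudotimeOrder:
    """Order embryos along the lineage path, youngest first.

    Orientation rule: of the two path-end clusters, the one with the
    lower mean summed marker expression starts the ordering (zygotic
    markers accumulate with age, so low marker expression means young).
    """
    path = _path_order(tree)
    scores = _marker_scores(nm, early_markers)
    assignment = tree.assignment
    cluster_mean = scores.groupby(assignment["cluster"]).mean()
    if cluster_mean[path[0]] > cluster_mean[path[-1]]:
        path = path[::-1]
    pos = {cl: i for i, cl in enumerate(path)}

    coords = []
    for row in assignment.itertuples(index=False):
        i = pos[row.cluster]
        j = pos[row.edge_b]
        coord = i + row.s if j > i else i - row.s
        coords.append((row.embryo_id, row.cluster, coord))
    order = pd.DataFrame(coords, columns=["embryo_id", "cluster", "coord"])
    order = order.sort_values(
        ["coord", "embryo_id"], kind="mergesort"
    ).reset_index(drop=True)
    order["rank"] = np.arange(1, len(order) + 1)
    order = order[["embryo_id", "rank", "cluster", "coord"]].set_index(
        "embryo_id", drop=False
    )
    anchor = ",".join(sorted(g for g in early_markers if g in nm.gene_ids)[:3])
    return PseudotimeOrder(order=order, path=path, direction_anchor=anchor)


def call_fertilization(
    nm: NormalizedMatrix,
    order: PseudotimeOrder,
    early_markers,
    score_threshold: float = 1.0,
    rank_cutoff: float = 0.25,
) -> pd.DataFrame:
    """Classify embryos as fertilized / unfertilized / indeterminate.

    An embryo is unfertilized when its summed normalized expression over
    the early-zygotic marker set stays below ``score_threshold`` even
    though it sits beyond ``rank_cutoff`` of the pseudo-time (old enough
    that fertilized embryos have switched the markers on).  Low-marker
    embryos below the cutoff are merely young: indeterminate.
    """
    if set(order.ranks.index) != set(nm.embryo_ids):
        raise ValueError("pseudotime order does not cover the matrix embryos")
    scores = _marker_scores(nm, early_markers)
    pct = order.rank_percentile()
    status = []
    for emb in nm.embryo_ids:
        low = scores[emb] < score_threshold
        if low and pct[emb] > rank_cutoff:
            status.append("unfertilized")
        elif low:
            status.append("indeterminate")
        else:
            status.append("fertilized")
    return pd.DataFrame(
        {
            "embryo_id": nm.embryo_ids,
            "status": status,
            "marker_score": scores[nm.embryo_ids].to_numpy(),
            "rank_percentile": pct[nm.embryo_ids].to_numpy(),
        }
    ).set_index("embryo_id", drop=False)


def crosstab_order_vs_window(
    order: PseudotimeOrder, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Pseudo-time quartile x collection-window embryo counts.

    ``metadata`` must carry a ``collection_window`` label per ordered
    embryo.  Quartile Q1 holds the earliest-ranked quarter.
    """
    ranks = order.ranks
    missing = [e for e in ranks.index if e not in metadata.index]
    if missing:
        raise ValueError(f"embryos missing collection-window labels: {missing}")
    windows = metadata.loc[ranks.index, "collection_window"]
    quart = pd.qcut(ranks, 4, labels=["Q1", "Q2", "Q3", "Q4"])
    table = pd.crosstab(quart, windows)
    table.index.name = "quartile"
    table.columns.name = "collection_window"
    return table
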