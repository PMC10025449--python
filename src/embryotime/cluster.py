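"""PAM k-medoids clustering over a precomputed distance matrix.

`KMedoids` is a scikit-learn-compatible estimator (BaseEstimator /
ClusterMixin) so it composes with sklearn model selection; the
module-level `kmedoids` / `select_k` functions are the thin wrappers the
rest of the pipeline uses.  The algorithm is classic PAM: a greedy build
phase followed by best-improvement swaps until the total within-cluster
cost stops decreasing.  All tie-breaks are by lowest index, so the fit
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from .matrix import DistanceMatrix

__all__ = ["KMedoids", "Clustering", "kmedoids", "select_k"]


class KMedoids(ClusterMixin, BaseEstimator):
    """k-medoids clustering on a precomputed distance matrix.

    Parameters
    ----------
    n_clusters : int
        Number of clusters (medoids) to select.
    max_iter : int
        Cap on swap iterations; PAM converges long before this on
        cohort-sized inputs.
    random_state : int or None
        Accepted for sklearn API compatibility.  The PAM build and swap
        phases used here are deterministic (lowest-index tie-breaks), so
        the seed does not influence the result.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster index (0-based) per sample.
    medoid_indices_ : ndarray of shape (n_clusters,)
        Sample indices chosen as medoids, sorted ascending.
    inertia_ : float
        Total within-cluster distance to the assigned medoid.
    n_iter_ : int
        Number of swap iterations performed.
    """

    def __init__(self, n_clusters: int = 8, max_iter: int = 300, random_state=None):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        D = np.asarray(X, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("X must be a square precomputed distance matrix")
        n = D.shape[0]
        k = self.n_clusters
        if not 2 <= k <= n:
            if k == n == 1:
                pass
            elif k > n:
                raise ValueError(f"n_clusters={k} exceeds n_samples={n}")
            elif k < 1:
                raise ValueError("n_clusters must be >= 1")

        # small instances: deterministic multi-start (greedy build forced
        # through each sample) makes the local search reliably optimal
        starts = range(n) if n <= 12 else (None,)
        best_pair = None
        for first in starts:
            medoids, cost, n_iter = self._pam(D, k, first)
            if best_pair is None or cost < best_pair[1] - 1e-12:
                best_pair = (medoids, cost, n_iter)
        medoids, cost, n_iter = best_pair
        medoids = np.sort(medoids)
        self.medoid_indices_ = medoids
        self.labels_ = np.argmin(D[:, medoids], axis=1)
        # medoids always belong to their own cluster even under distance ties
        self.labels_[medoids] = np.arange(k)
        self.inertia_ = float(self._cost(D, medoids))
        self.n_iter_ = n_iter
        return self

    def _pam(self, D, k, first=None):
        n = D.shape[0]
        medoids = self._build(D, k, first)
        cost = self._cost(D, medoids)
        n_iter = 0
        while n_iter < self.max_iter:
            best = None  # (new_cost, medoid_pos, candidate)
            med_set = set(medoids.tolist())
            for pos in range(k):
                for cand in range(n):
                    if cand in med_set:
                        continue
                    trial = medoids.copy()
                    trial[pos] = cand
                    c = self._cost(D, trial)
                    if c < cost - 1e-12 and (best is None or c < best[0] - 1e-12):
                        best = (c, pos, cand)
            if best is None:
                break
            cost = best[0]
            medoids[best[1]] = best[2]
            n_iter += 1
        return medoids, cost, n_iter

    @staticmethod
    def _cost(D: np.ndarray, medoids: np.ndarray) -> float:
        return float(D[:, medoids].min(axis=1).sum())

    @staticmethod
    def _build(D: np.ndarray, k: int, first: int | None = None) -> np.ndarray:
        n = D.shape[0]
        if first is None:
            first = int(np.argmin(D.sum(axis=1)))
        medoids = [first]
        nearest = D[:, first].copy()
        while len(medoids) < k:
            gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
            gains[medoids] = -np.inf
            nxt = int(np.argmax(gains))
            medoids.append(nxt)
            nearest = np.minimum(nearest, D[:, nxt])
        return np.array(sorted(medoids))


@dataclass(frozen=True)
class Clustering:
    """k-medoids result keyed by embryo id; cluster indices run 1..k."""

    labels: pd.Series
    medoid_ids: list[str]
    k: int
    total_cost: float

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def medoid_of(self, cluster: int) -> str:
        return self.medoid_ids[cluster - 1]


def kmedoids(d: DistanceMatrix, k: int, seed: int | None = None) -> Clustering:
    """Cluster a distance matrix into ``k`` groups by PAM."""
    if k > d.n_embryos:
        raise ValueError(f"k={k} exceeds the {d.n_embryos} embryos available")
    est = KMedoids(n_clusters=k, random_state=seed).fit(d.values.to_numpy())
    labels = pd.Series(est.labels_ + 1, index=d.embryo_ids, name="cluster")
    medoid_ids = [str(d.embryo_ids[i]) for i in est.medoid_indices_]
    return Clustering(labels=labels, medoid_ids=medoid_ids, k=k, total_cost=est.inertia_)


def select_k(
    d: DistanceMatrix, k_range, seed: int | None = None
) -> tuple[int, dict[int, float]]:
    """Pick k by maximal mean silhouette width (ties -> smallest k)."""
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range is empty")
    n = d.n_embryos
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    D = d.values.to_numpy()
    scores: dict[int, float] = {}
    for k in k_range:
        labels = KMedoids(n_clusters=k, random_state=seed).fit(D).labels_
        scores[k] = float(silhouette_score(D, labels, metric="precomputed"))
    best = max(scores.values())
    chosen = min(k for k, s in scores.items() if s >= best - 1e-12)
    return chosen, scores
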