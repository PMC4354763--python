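"""Weighted k-means and k-medoids partitioning with a multi-start protocol.

Both algorithms optimize (heuristically) the within-cluster dispersion

    Σ_k [ Σ_{i,j ∈ cluster k} d_ij² ] / n_k   →   min,

where the inner sum runs over *ordered* pairs and ``d`` is the chosen
weighted metric. Each random start draws a random initial partition
(uniform cluster labels, repaired to keep every cluster non-empty) for
k-means, or random distinct initial medoids for k-medoids; the best of
``n_starts`` converged runs by the objective above is returned. Everything
is deterministic given the seed, and the starts of a run are drawn
sequentially, so the best-of-``s`` objective is non-increasing in ``s`` for
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import cosine_matrix, euclidean_matrix, METRICS
from .encoders import EncodingResult

__all__ = [
    "Partition",
    "ClusterRun",
    "objective",
    "kmeans_weighted",
    "kmedoids_weighted",
    "run_algorithm",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of each workflow to one of K non-empty clusters.

    Labels are stored 0-based (``0..K-1``); the CSV export writes the
    conventional 1-based cluster numbers.
    """

    ids: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "ids", tuple(self.ids))
        if lab.shape != (len(self.ids),):
            raise ValueError("labels length inconsistent with id list")
        if len(self.ids) == 0:
            raise ValueError("empty partition")
        k = lab.max() + 1
        present = np.bincount(lab, minlength=k)
        if lab.min() < 0 or (present == 0).any():
            raise ValueError("cluster labels must cover 0..K-1 with no empty cluster")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def K(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def clusters(self) -> list[list[str]]:
        return [[self.ids[i] for i in self.members(k)] for k in range(self.K)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"workflow_id": list(self.ids), "cluster": self.labels + 1}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ClusterRun:
    """One converged partitioning run (best of its starts).

    ``centers`` holds centroid coordinates (K × m array) for k-means and
    medoid element indices (length-K integer array) for k-medoids.
    """

    partition: Partition
    objective: float
    centers: np.ndarray
    algorithm: str  # "kmeans" | "kmedoids"
    metric: str
    n_iterations: int
    seed: int | None = None

    def center_matrix(self, X: np.ndarray) -> np.ndarray:
        """Cluster centers as a K × m coordinate matrix."""
        if self.algorithm == "kmedoids":
            return X[np.asarray(self.centers, dtype=int)]
        return np.asarray(self.centers, dtype=float)


def _pairwise_sq(enc: EncodingResult, metric: str) -> np.ndarray:
    X = enc.matrix.T
    if metric == "euclidean":
        D = euclidean_matrix(X, enc.weights)
    elif metric == "cosine":
        D = cosine_matrix(X, enc.weights)
    else:
        raise ValueError(f"unknown metric: {metric!r} (expected one of {METRICS})")
    return D * D


def objective_from_sq(D2: np.ndarray, labels: np.ndarray) -> float:
    """Eq-style dispersion from a precomputed squared-distance matrix."""
    total = 0.0
    for k in range(labels.max() + 1):
        idx = np.flatnonzero(labels == k)
        total += D2[np.ix_(idx, idx)].sum() / len(idx)
    return float(total)


def objective(enc: EncodingResult, part: Partition, metric: str = "euclidean") -> float:
    """Within-cluster dispersion Σ_k (Σ ordered-pair d²) / n_k."""
    if tuple(part.ids) != tuple(enc.workflow_ids):
        raise ValueError("partition ids do not match the encoding's workflows")
    return objective_from_sq(_pairwise_sq(enc, metric), part.labels)


def _point_center_dist(X: np.ndarray, C: np.ndarray, w: np.ndarray,
                       metric: str) -> np.ndarray:
    """n × K distances from points (rows of X) to centers (rows of C)."""
    if metric == "euclidean":
        diff = X[:, None, :] - C[None, :, :]
        return np.sqrt(np.einsum("nkm,m,nkm->nk", diff, w, diff))
    # weighted cosine, with the zero-norm convention of the distances module
    inner = (X * w) @ C.T
    nx = np.sqrt(np.einsum("nm,m,nm->n", X, w, X))
    nc = np.sqrt(np.einsum("km,m,km->k", C, w, C))
    zx, zc = nx == 0.0, nc == 0.0
    denom = np.outer(np.where(zx, 1.0, nx), np.where(zc, 1.0, nc))
    D = 1.0 - inner / denom
    if zx.any() or zc.any():
        D[zx, :] = 1.0
        D[:, zc] = 1.0
        D[np.ix_(zx, zc)] = 0.0
    return np.maximum(D, 0.0)


def _repair_empty(labels: np.ndarray, K: int, dist_to_center: np.ndarray | None,
                  D2: np.ndarray) -> np.ndarray:
    """Keep every cluster non-empty.

    The element farthest from its current center is moved into the empty
    cluster (ties → lowest element index). When center distances are not
    available (initial random assignment), the farthest-by-pairwise-sum
    element of the largest cluster is used.
    """
    labels = labels.copy()
    for k in range(K):
        while not (labels == k).any():
            movable = np.flatnonzero(np.bincount(labels, minlength=K)[labels] > 1)
            if dist_to_center is not None:
                d = dist_to_center[movable, labels[movable]]
            else:
                d = np.array([D2[i, labels == labels[i]].sum() for i in movable])
            pick = movable[int(np.argmax(d))]  # argmax keeps first (lowest index) tie
            labels[pick] = k
    return labels


def _kmeans_single(X: np.ndarray, w: np.ndarray, K: int, metric: str,
                   D2: np.ndarray, rng: np.random.Generator,
                   max_iter: int) -> tuple[np.ndarray, np.ndarray, int]:
    n = X.shape[0]
    labels = _repair_empty(rng.integers(0, K, size=n), K, None, D2)
    C = np.empty((K, X.shape[1]))
    for it in range(1, max_iter + 1):
        for k in range(K):
            C[k] = X[labels == k].mean(axis=0)
        dist = _point_center_dist(X, C, w, metric)
        new = _repair_empty(np.argmin(dist, axis=1), K, dist, D2)
        if np.array_equal(new, labels):
            return labels, C, it
        labels = new
    for k in range(K):
        C[k] = X[labels == k].mean(axis=0)
    return labels, C, max_iter


def _kmedoids_single(K: int, D: np.ndarray, D2: np.ndarray,
                     rng: np.random.Generator,
                     max_iter: int) -> tuple[np.ndarray, np.ndarray, int]:
    n = D.shape[0]
    medoids = np.sort(rng.choice(n, size=K, replace=False))
    for it in range(1, max_iter + 1):
        dist = D[:, medoids]
        labels = _repair_empty(np.argmin(dist, axis=1), K, dist, D2)
        labels[medoids] = np.arange(K)  # a medoid stays in its own cluster
        new = medoids.copy()
        for k in range(K):
            idx = np.flatnonzero(labels == k)
            within = D[np.ix_(idx, idx)].sum(axis=1)
            new[k] = idx[int(np.argmin(within))]  # ties → lowest index
        if np.array_equal(new, medoids):
            return labels, medoids, it
        medoids = new
    dist = D[:, medoids]
    labels = _repair_empty(np.argmin(dist, axis=1), K, dist, D2)
    return labels, medoids, max_iter


def _check_k(K: int, n: int) -> None:
    if K < 1:
        raise ValueError(f"K must be at least 1, got {K}")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of workflows n={n}")


def kmeans_weighted(enc: EncodingResult, K: int, metric: str = "euclidean",
                    n_starts: int = 1, max_iter: int = 300,
                    seed: int | None = None) -> ClusterRun:
    """Best-of-``n_starts`` weighted k-means (Lloyd iterations).

    Each start draws a random initial partition; centroids are arithmetic
    means of member columns, reassignment is by the chosen weighted distance
    to the centroids, and iteration stops when assignments are stable. Runs
    are ranked by the ordered-pair dispersion objective.
    """
    _check_k(K, enc.n_workflows)
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    X, w = enc.matrix.T, enc.weights
    D2 = _pairwise_sq(enc, metric)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        labels, C, iters = _kmeans_single(X, w, K, metric, D2, rng, max_iter)
        obj = objective_from_sq(D2, labels)
        if best is None or obj < best[0] - 1e-12:
            best = (obj, labels, C.copy(), iters)
    obj, labels, C, iters = best
    return ClusterRun(Partition(enc.workflow_ids, labels), obj, C,
                      "kmeans", metric, iters, seed)


def kmedoids_weighted(enc: EncodingResult, K: int, metric: str = "euclidean",
                      n_starts: int = 1, max_iter: int = 300,
                      seed: int | None = None) -> ClusterRun:
    """Best-of-``n_starts`` k-medoids (Voronoi iteration).

    Random distinct initial medoids; elements are assigned to the nearest
    medoid and each medoid is updated to the member minimizing the
    within-cluster distance sum (ties → lowest index).
    """
    _check_k(K, enc.n_workflows)
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    D2 = _pairwise_sq(enc, metric)
    D = np.sqrt(D2)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        labels, medoids, iters = _kmedoids_single(K, D, D2, rng, max_iter)
        obj = objective_from_sq(D2, labels)
        if best is None or obj < best[0] - 1e-12:
            best = (obj, labels, medoids.copy(), iters)
    obj, labels, medoids, iters = best
    return ClusterRun(Partition(enc.workflow_ids, labels), obj, medoids,
                      "kmedoids", metric, iters, seed)


def run_algorithm(enc: EncodingResult, algorithm: str, K: int,
                  metric: str = "euclidean", n_starts: int = 1,
                  max_iter: int = 300, seed: int | None = None) -> ClusterRun:
    """Dispatch to :func:`kmeans_weighted` or :func:`kmedoids_weighted`."""
    if algorithm == "kmeans":
        return kmeans_weighted(enc, K, metric, n_starts, max_iter, seed)
    if algorithm == "kmedoids":
        return kmedoids_weighted(enc, K, metric, n_starts, max_iter, seed)
    raise ValueError(f"unknown algorithm: {algorithm!r}")
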