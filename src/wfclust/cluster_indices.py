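"""Cluster-validity indices and selection of the number of clusters K.

Three indices are provided, all metric-consistent (squared weighted
Euclidean or squared weighted cosine distances to the cluster centers):

* **Calinski–Harabasz**:  CH(K) = (SS_B / SS_W) · (n − K)/(K − 1), where
  SS_B = Σ_k n_k ‖center_k − center‖² and
  SS_W = Σ_k Σ_{i∈k} ‖x_i − center_k‖². Higher is better; the K with the
  largest CH is selected.
* **logSS**:  logSS(K) = ln(SS_B / SS_W). The selected K minimizes the
  consecutive difference logSS(K+1) − logSS(K) (signed, as published;
  an absolute-difference variant is available behind a flag).
* **Silhouette**:  s(i) = (b(i) − a(i)) / max(a(i), b(i)) per element,
  averaged per cluster and then macro-averaged over clusters (the published
  form; the more common per-point mean is available behind a flag).
  Higher is better.

Cluster centers follow the partitioning algorithm: centroids for k-means
runs and medoids for k-medoids runs; the overall center is the grand
centroid resp. the global medoid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .distances import cosine_matrix, euclidean_matrix
from .encoders import EncodingResult
from .partitioning import (ClusterRun, Partition, _pairwise_sq,
                           _point_center_dist, run_algorithm)

__all__ = [
    "DegenerateClusteringError",
    "ch_index",
    "logss_index",
    "logss_choose_k",
    "silhouette_index",
    "KSelection",
    "select_k",
]


class DegenerateClusteringError(ValueError):
    """Raised when an index is undefined (e.g. zero within-cluster variance)."""


def _scatter(enc: EncodingResult, run: ClusterRun,
             metric: str) -> tuple[float, float]:
    """(SS_B, SS_W) with metric-consistent squared distances to the centers."""
    X, w = enc.matrix.T, enc.weights
    part = run.partition
    C = run.center_matrix(X)
    if run.algorithm == "kmedoids":
        # overall center = global medoid: element minimizing the total
        # distance sum to all elements (ties -> lowest index)
        D = np.sqrt(_pairwise_sq(enc, metric))
        grand = X[int(np.argmin(D.sum(axis=1)))]
    else:
        grand = X.mean(axis=0)
    d_center = _point_center_dist(X, C, w, metric)
    ssw = float(np.sum(d_center[np.arange(part.n), part.labels] ** 2))
    d_grand = _point_center_dist(C, grand[None, :], w, metric)[:, 0]
    ssb = float(np.sum(part.sizes * d_grand ** 2))
    return ssb, ssw


def _check_k_range(K: int, n: int) -> None:
    if not 2 <= K <= n - 1:
        raise DegenerateClusteringError(
            f"index undefined for K={K}: K must lie in [2, n-1] (n={n})")


def ch_index(enc: EncodingResult, run: ClusterRun, metric: str | None = None) -> float:
    """Calinski–Harabasz index of a converged run (higher is better)."""
    metric = metric or run.metric
    n, K = run.partition.n, run.partition.K
    _check_k_range(K, n)
    ssb, ssw = _scatter(enc, run, metric)
    if ssw <= 0.0:
        raise DegenerateClusteringError("degenerate: zero within-cluster variance")
    return ssb / ssw * (n - K) / (K - 1)


def logss_index(enc: EncodingResult, run: ClusterRun, metric: str | None = None) -> float:
    """Natural-log ratio ln(SS_B / SS_W) of a converged run."""
    metric = metric or run.metric
    _check_k_range(run.partition.K, run.partition.n)
    ssb, ssw = _scatter(enc, run, metric)
    if ssw <= 0.0:
        raise DegenerateClusteringError("degenerate: zero within-cluster variance")
    if ssb <= 0.0:
        raise DegenerateClusteringError("degenerate: zero between-cluster variance")
    return math.log(ssb / ssw)


def logss_choose_k(per_k: Mapping[int, float], absolute: bool = False) -> int:
    """K with the smallest consecutive difference logSS(K+1) − logSS(K).

    ``per_k`` maps each scanned K to its logSS value; consecutive pairs
    (K, K+1) are compared and the K of the smallest (signed, or absolute
    with ``absolute=True``) difference is returned; ties break toward the
    smaller K. With a single scanned K, that K is returned.
    """
    ks = sorted(per_k)
    if not ks:
        raise ValueError("empty scan range")
    if len(ks) == 1:
        return ks[0]
    best_k, best_diff = None, None
    for k in ks[:-1]:
        if k + 1 not in per_k:
            continue
        diff = per_k[k + 1] - per_k[k]
        if absolute:
            diff = abs(diff)
        if best_diff is None or diff < best_diff - 1e-15:
            best_k, best_diff = k, diff
    if best_k is None:  # non-contiguous scan: fall back to smallest K
        return ks[0]
    return best_k


def silhouette_index(enc: EncodingResult, part: Partition,
                     metric: str = "euclidean", per_point: bool = False) -> float:
    """Mean Silhouette width of a partition (−1 … 1, higher is better).

    ``a(i)`` is the mean distance of element i to its co-members, ``b(i)``
    the smallest mean distance to another cluster; singleton elements get
    s(i) = 0. By default per-cluster means s(k) are macro-averaged over
    clusters; ``per_point=True`` averages s(i) over elements instead.
    """
    n, K = part.n, part.K
    _check_k_range(K, n)
    D = np.sqrt(_pairwise_sq(enc, metric))
    s = np.zeros(n)
    sizes = part.sizes
    for i in range(n):
        k = part.labels[i]
        if sizes[k] == 1:
            continue  # singleton convention: s(i) = 0
        a = D[i, part.labels == k].sum() / (sizes[k] - 1)
        b = min(D[i, part.labels == c].mean() for c in range(K) if c != k)
        m = max(a, b)
        if m > 0:
            s[i] = (b - a) / m
    if per_point:
        return float(s.mean())
    return float(np.mean([s[part.labels == k].mean() for k in range(K)]))


_INDEX_NAMES = ("CH", "SI", "logSS")
# higher-is-better indices choose argmax; logSS uses the consecutive rule
_ALIASES = {"ch": "CH", "si": "SI", "sil": "SI", "silhouette": "SI",
            "logss": "logSS"}


def normalize_index_name(name: str) -> str:
    out = _ALIASES.get(name.lower(), name)
    if out not in _INDEX_NAMES:
        raise ValueError(f"unknown clustering index: {name!r}")
    return out


@dataclass(frozen=True)
class KSelection:
    """Outcome of a K scan: per-K index values/runs and the chosen K."""

    index_name: str
    per_k: dict[int, tuple[float, ClusterRun]]
    chosen_k: int
    ss_b: dict[int, float] = field(default_factory=dict)
    ss_w: dict[int, float] = field(default_factory=dict)

    @property
    def chosen_partition(self) -> Partition:
        return self.per_k[self.chosen_k][1].partition

    @property
    def chosen_run(self) -> ClusterRun:
        return self.per_k[self.chosen_k][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "K": k,
                "index_value": val,
                "objective": run.objective,
                "ss_b": self.ss_b.get(k, float("nan")),
                "ss_w": self.ss_w.get(k, float("nan")),
                "chosen": k == self.chosen_k,
            }
            for k, (val, run) in sorted(self.per_k.items())
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "index": self.index_name,
                "chosen_k": self.chosen_k,
                "per_k": {
                    str(k): {"index_value": val, "objective": run.objective}
                    for k, (val, run) in sorted(self.per_k.items())
                },
            },
            indent=2,
        )


def select_k(enc: EncodingResult, algorithm: str = "kmeans",
             metric: str = "euclidean", index_name: str = "CH",
             k_min: int = 2, k_max: int | None = None, n_starts: int = 100,
             max_iter: int = 300, seed: int | None = None) -> KSelection:
    """Scan K, run best-of-``n_starts`` partitioning per K, pick K by index.

    CH and Silhouette select the K of their largest value (a partition with
    zero within-cluster variance counts as perfectly separated: CH/logSS are
    treated as +inf and ties break toward the smaller K). logSS applies its
    consecutive-difference rule. Deterministic given ``seed``.
    """
    n = enc.n_workflows
    index_name = normalize_index_name(index_name)
    if k_max is None:
        k_max = n - 1
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(
            f"empty or invalid scan range [{k_min}, {k_max}] for n={n}")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(k_max - k_min + 1)]
    per_k: dict[int, tuple[float, ClusterRun]] = {}
    ss_b: dict[int, float] = {}
    ss_w: dict[int, float] = {}
    for K, kseed in zip(range(k_min, k_max + 1), child_seeds):
        run = run_algorithm(enc, algorithm, K, metric, n_starts, max_iter, kseed)
        ssb, ssw = _scatter(enc, run, metric)
        ss_b[K], ss_w[K] = ssb, ssw
        if index_name == "SI":
            val = silhouette_index(enc, run.partition, metric)
        elif ssw <= 0.0:
            val = float("inf")  # perfectly separated partition
        elif index_name == "CH":
            val = ssb / ssw * (n - K) / (K - 1)
        else:
            val = math.log(ssb / ssw) if ssb > 0 else float("-inf")
        per_k[K] = (val, run)
    if index_name == "logSS":
        chosen = logss_choose_k({k: v for k, (v, _) in per_k.items()})
    else:
        chosen = max(sorted(per_k), key=lambda k: per_k[k][0])
        # ties (incl. multiple +inf) -> smallest K
        best = per_k[chosen][0]
        for k in sorted(per_k):
            if per_k[k][0] >= best - 1e-15 or (math.isinf(best) and
                                               math.isinf(per_k[k][0])):
                chosen = k
                break
    return KSelection(index_name, per_k, chosen, ss_b, ss_w)
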