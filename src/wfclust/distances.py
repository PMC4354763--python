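"""Weighted Euclidean and weighted cosine distances between workflows.

Both distances act on the columns of an encoding matrix ``W`` with
per-variable weights ``y``:

* Euclidean:  d(i, j) = sqrt( Σ_p  y_p (w_ip − w_jp)² )
* Cosine:     d(i, j) = 1 − Σ_p y_p w_ip w_jp /
              ( sqrt(Σ_p y_p w_ip²) · sqrt(Σ_p y_p w_jp²) )

For non-negative data the cosine distance lies in [0, 1]. Columns with zero
weighted norm use a total, symmetric convention: the distance between two
zero-norm columns is 0, between a zero-norm and a non-zero column 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoders import EncodingResult

__all__ = [
    "DistanceMatrix",
    "weighted_euclidean",
    "weighted_cosine",
    "distance_matrix",
    "euclidean_matrix",
    "cosine_matrix",
    "read_distance_csv",
]

METRICS = ("euclidean", "cosine")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between workflows with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric_tag: str = "euclidean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with id list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids),
                            columns=list(self.ids))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def read_distance_csv(path: str | Path, metric_tag: str = "euclidean") -> DistanceMatrix:
    """Read a square distance matrix CSV (header row and id column)."""
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(tuple(str(c) for c in df.columns),
                          df.to_numpy(dtype=float), metric_tag)


def _check_index(enc: EncodingResult, i: int) -> None:
    if not 0 <= i < enc.n_workflows:
        raise IndexError(f"workflow index {i} out of range (n={enc.n_workflows})")


def weighted_euclidean(enc: EncodingResult, i: int, j: int) -> float:
    """Weighted Euclidean distance between workflow columns ``i`` and ``j``."""
    _check_index(enc, i)
    _check_index(enc, j)
    diff = enc.matrix[:, i] - enc.matrix[:, j]
    return float(np.sqrt(np.sum(enc.weights * diff * diff)))


def weighted_cosine(enc: EncodingResult, i: int, j: int) -> float:
    """Weighted cosine distance between workflow columns ``i`` and ``j``."""
    _check_index(enc, i)
    _check_index(enc, j)
    w = enc.weights
    xi, xj = enc.matrix[:, i], enc.matrix[:, j]
    ni = np.sqrt(np.sum(w * xi * xi))
    nj = np.sqrt(np.sum(w * xj * xj))
    if ni == 0.0 and nj == 0.0:
        return 0.0
    if ni == 0.0 or nj == 0.0:
        return 1.0
    return float(1.0 - np.sum(w * xi * xj) / (ni * nj))


def euclidean_matrix(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """All pairwise weighted Euclidean distances between rows of ``X``."""
    Z = X * np.sqrt(w)
    sq = np.sum(Z * Z, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def cosine_matrix(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """All pairwise weighted cosine distances between rows of ``X``.

    Zero-norm rows follow the module's convention (0 between two zero-norm
    rows, 1 against any non-zero row).
    """
    G = (X * w) @ X.T
    nrm = np.sqrt(np.maximum(np.diag(G), 0.0))
    zero = nrm == 0.0
    denom = np.where(zero, 1.0, nrm)
    C = G / denom[:, None] / denom[None, :]
    D = 1.0 - C
    if zero.any():
        D[zero, :] = 1.0
        D[:, zero] = 1.0
        D[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(D, 0.0)
    np.maximum(D, 0.0, out=D)
    return D


def distance_matrix(enc: EncodingResult, metric: str = "euclidean") -> DistanceMatrix:
    """Full pairwise :class:`DistanceMatrix` over an encoding."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric: {metric!r} (expected one of {METRICS})")
    if enc.n_workflows < 2:
        raise ValueError("a distance matrix needs at least 2 workflows")
    X = enc.matrix.T  # workflows as points
    if metric == "euclidean":
        D = euclidean_matrix(X, enc.weights)
    else:
        D = cosine_matrix(X, enc.weights)
    D = (D + D.T) / 2.0  # exact symmetry against fp round-off
    return DistanceMatrix(enc.workflow_ids, D, metric)
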