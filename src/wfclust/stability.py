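"""Pairwise (PS) and global (PSG) clustering-stability indices.

k-means and k-medoids started from different random partitions typically
converge to different local optima. Over Q independent randomized runs the
*pairwise support* PS(w_i, w_j) is the fraction of runs in which two
elements are co-clustered, and the *singleton support* PS(w_i) (stored on
the matrix diagonal) is the fraction of runs in which an element forms a
cluster by itself. Both are frequencies in [0, 1].

The aggregate PSG scores reward decisive behaviour — a pair always together
or always apart contributes max(PS, 1 − PS) = 1 — and penalize pairs near
PS = 1/2:

    PSG(W)   = ( 2 Σ_{i<j} max(PS_ij, 1 − PS_ij)
                 + Σ_i max(PS_i, 1 − PS_i) ) / n²,
    PSG(w_i) = ( Σ_{j≠i} max(PS_ij, 1 − PS_ij)
                 + max(PS_i, 1 − PS_i) ) / n.

Both range from 0.5 (maximal instability: every frequency at 1/2) to 1
(full stability). Each of the Q runs re-selects its own number of clusters
with a validity index, so the supports also capture ambiguity in K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster_indices import normalize_index_name, select_k
from .encoders import EncodingResult
from .partitioning import Partition

__all__ = [
    "RunRecord",
    "StabilityResult",
    "pairwise_support",
    "psg_global",
    "psg_individual",
    "stability_run",
]


@dataclass(frozen=True)
class RunRecord:
    """One randomized run: its partition, selected K and index value."""

    partition: Partition
    chosen_k: int
    index_value: float = float("nan")
    seed: int | None = None


def pairwise_support(runs: Sequence[RunRecord]) -> np.ndarray:
    """n × n support matrix over a collection of runs.

    Off-diagonal (i, j): fraction of runs with i and j co-clustered;
    diagonal (i, i): fraction of runs in which i is a singleton cluster.
    """
    if not runs:
        raise ValueError("at least one run is required")
    ids = tuple(runs[0].partition.ids)
    n = len(ids)
    ps = np.zeros((n, n))
    for r in runs:
        if tuple(r.partition.ids) != ids:
            raise ValueError("all runs must cover the same workflow ids")
        lab = r.partition.labels
        same = lab[:, None] == lab[None, :]
        ps += same
        sizes = r.partition.sizes
        np.fill_diagonal(ps, np.diag(ps) - 1 + (sizes[lab] == 1))
    return ps / len(runs)


def psg_global(ps: np.ndarray) -> float:
    """Global stability score of a support matrix (0.5 … 1)."""
    ps = np.asarray(ps, dtype=float)
    n = ps.shape[0]
    m = np.maximum(ps, 1.0 - ps)
    pair_sum = (m.sum() - np.trace(m)) / 2.0  # Σ_{i<j}
    diag_sum = float(np.trace(m))
    return float((2.0 * pair_sum + diag_sum) / (n * n))


def psg_individual(ps: np.ndarray, i: int) -> float:
    """Per-element stability score (0.5 … 1)."""
    ps = np.asarray(ps, dtype=float)
    n = ps.shape[0]
    m = np.maximum(ps[i], 1.0 - ps[i])
    return float((m.sum() - m[i] + max(ps[i, i], 1.0 - ps[i, i])) / n)


@dataclass(frozen=True)
class StabilityResult:
    """PS matrix with global and per-element PSG scores over Q runs."""

    ids: tuple[str, ...]
    ps: np.ndarray
    psg: float
    psg_per_element: np.ndarray
    Q: int
    settings: dict | None = None

    def ps_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ps, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path: str | Path) -> None:
        self.ps_frame().to_csv(path)

    def to_json(self) -> str:
        return json.dumps(
            {
                "Q": self.Q,
                "psg_global": self.psg,
                "psg_individual": dict(zip(self.ids,
                                           map(float, self.psg_per_element))),
                "settings": self.settings or {},
            },
            indent=2,
        )


def stability_run(enc: EncodingResult, algorithm: str = "kmeans",
                  metric: str = "cosine", index_name: str = "CH",
                  k_min: int = 2, k_max: int | None = None, Q: int = 1000,
                  seed: int | None = None,
                  keep_runs: bool = False) -> StabilityResult | tuple:
    """Estimate PS/PSG over Q independent randomized runs.

    Each run starts every candidate K from a single random partition,
    selects K with the chosen validity index and records the resulting
    partition. Deterministic given ``seed``. With ``keep_runs=True`` the
    individual :class:`RunRecord` list is returned alongside the result.
    """
    if Q < 1:
        raise ValueError("Q must be at least 1")
    index_name = normalize_index_name(index_name)
    ss = np.random.SeedSequence(seed)
    records: list[RunRecord] = []
    for child in ss.spawn(Q):
        run_seed = int(child.generate_state(1)[0] % (2**31))
        sel = select_k(enc, algorithm, metric, index_name,
                       k_min=k_min, k_max=k_max, n_starts=1, seed=run_seed)
        records.append(RunRecord(sel.chosen_partition, sel.chosen_k,
                                 sel.per_k[sel.chosen_k][0], run_seed))
    ps = pairwise_support(records)
    result = StabilityResult(
        ids=tuple(enc.workflow_ids),
        ps=ps,
        psg=psg_global(ps),
        psg_per_element=np.array([psg_individual(ps, i)
                                  for i in range(len(enc.workflow_ids))]),
        Q=Q,
        settings={
            "algorithm": algorithm, "metric": metric, "index": index_name,
            "k_min": k_min, "k_max": k_max, "seed": seed,
            "encoding_type": enc.encoding_type,
        },
    )
    if keep_runs:
        return result, records
    return result
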