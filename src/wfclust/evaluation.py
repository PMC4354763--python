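"""Evaluation against reference labels and synthetic workflow collections.

The plain Rand index measures agreement between a computed partition and a
reference classification as the fraction of element pairs treated the same
way by both (co-clustered in both, or separated in both). The synthetic
generator emulates collections like the worked five-workflow example at a
configurable scale: a task pool split into class-specific sub-pools,
pipeline-shaped topologies (chains with occasional branching), log-normal
execution times, class keywords as annotations, and a mixing probability ε
controlling how often a workflow borrows tasks from a foreign class. At
ε = 0 class task supports are disjoint and the classes are perfectly
recoverable; growing ε degrades recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster_indices import select_k
from .encoders import KeywordRule, encode
from .partitioning import Partition
from .workflow_model import PortSpec, Task, Workflow, WorkflowSet

__all__ = [
    "rand_index",
    "labels_to_partition",
    "SimConfig",
    "simulate_workflows",
    "experiment_grid",
    "rand_by_task_count",
]


def labels_to_partition(labels: Mapping[str, str],
                        ids: Sequence[str] | None = None) -> Partition:
    """Build a :class:`Partition` from an id → class-label mapping."""
    ids = tuple(ids) if ids is not None else tuple(labels)
    classes = sorted({str(labels[i]) for i in ids})
    lut = {c: k for k, c in enumerate(classes)}
    return Partition(ids, np.array([lut[str(labels[i])] for i in ids]))


def rand_index(p1: Partition, p2: Partition) -> float:
    """Plain (unadjusted) Rand index between two partitions of the same ids.

    RI = (a + d) / C(n, 2) with a = pairs co-clustered in both partitions
    and d = pairs separated in both; RI ∈ [0, 1], 1 for identical
    partitions. Partitions may have different numbers of clusters.
    """
    if set(p1.ids) != set(p2.ids):
        raise ValueError("partitions must cover the same workflow ids")
    order = {wid: i for i, wid in enumerate(p1.ids)}
    l1 = p1.labels
    l2 = np.empty_like(l1)
    for wid, lab in zip(p2.ids, p2.labels):
        l2[order[wid]] = lab
    n = len(l1)
    if n < 2:
        return 1.0
    # contingency-based pair counting
    cont = pd.crosstab(l1, l2).to_numpy()
    a = sum(comb(int(x), 2) for x in cont.ravel())
    same1 = sum(comb(int(x), 2) for x in cont.sum(axis=1))
    same2 = sum(comb(int(x), 2) for x in cont.sum(axis=0))
    total = comb(n, 2)
    d = total - same1 - same2 + a
    return (a + d) / total


# --------------------------------------------------------------------------
# Synthetic workflow collections
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic workflow-collection generator.

    Defaults emulate the structure of the real collection the method was
    developed on: four workflow classes over a pool of ~16 tasks (four per
    class), pipelines of up to eight tasks, and per-class annotation
    keywords. ``mixing`` is the probability ε that a task slot is filled
    from a uniformly chosen foreign class pool instead of the workflow's own.
    Execution times are log-normal (parameters on the log scale), roughly
    matching the sub-second to ~1 time-unit range of the worked example.
    """

    n_classes: int = 4
    tasks_per_class: int = 4
    n_workflows_per_class: int = 30
    tasks_per_workflow: tuple[int, int] = (1, 8)
    mixing: float = 0.0
    exec_time_lognormal: tuple[float, float] = (-0.7, 0.6)
    keyword_classes: Mapping[str, str] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing probability must lie in [0, 1]")
        for name in ("n_classes", "tasks_per_class", "n_workflows_per_class"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        lo, hi = self.tasks_per_workflow
        if not 1 <= lo <= hi:
            raise ValueError("invalid tasks_per_workflow range")
        if hi > self.n_classes * self.tasks_per_class:
            raise ValueError(
                "tasks_per_workflow maximum exceeds the total task pool size")

    def class_names(self) -> list[str]:
        return [f"class{c + 1}" for c in range(self.n_classes)]

    def keyword_for(self, cls: str) -> str:
        if self.keyword_classes is not None:
            return self.keyword_classes[cls]
        return f"kw_{cls}"


def simulate_workflows(cfg: SimConfig) -> WorkflowSet:
    """Generate a labelled synthetic workflow collection.

    Workflow classes are assigned round-robin; each workflow draws its task
    count uniformly from ``tasks_per_workflow`` and fills the slots with
    distinct tasks, each taken from its own class pool with probability
    1 − ε and from a uniformly chosen foreign pool otherwise (the count is
    capped by the distinct tasks obtainable this way, so ε = 0 workflows
    never leave their class pool). Topology is a chain with occasional
    branching: every instance after the first receives an edge from a
    uniformly chosen earlier instance. Execution times are drawn once per
    pool task; class keywords are attached to the tasks of the class pool.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = cfg.class_names()
    mu, sigma = cfg.exec_time_lognormal
    pools: dict[str, list[str]] = {}
    pool_tasks: list[Task] = []
    for cls in classes:
        ids = [f"{cls}_task{t + 1}" for t in range(cfg.tasks_per_class)]
        pools[cls] = ids
        for tid in ids:
            pool_tasks.append(Task(
                id=tid,
                name=tid,
                category=cls,
                avg_exec_time=float(rng.lognormal(mu, sigma)),
                annotations=frozenset({cfg.keyword_for(cls)}),
            ))
    lo, hi = cfg.tasks_per_workflow
    workflows: list[Workflow] = []
    total = cfg.n_classes * cfg.n_workflows_per_class
    for w_idx in range(total):
        cls = classes[w_idx % cfg.n_classes]
        count = int(rng.integers(lo, hi + 1))
        chosen: list[str] = []
        used: set[str] = set()
        for _ in range(count):
            if cfg.mixing > 0 and rng.random() < cfg.mixing:
                foreign = [c for c in classes if c != cls]
                src = foreign[int(rng.integers(len(foreign)))]
            else:
                src = cls
            avail = [t for t in pools[src] if t not in used]
            if not avail:
                avail = [t for t in pools[cls] if t not in used]
            if not avail:
                break  # own pool exhausted; workflow stays shorter
            pick = avail[int(rng.integers(len(avail)))]
            chosen.append(pick)
            used.add(pick)
        edges = tuple(
            (int(rng.integers(i)), i) for i in range(1, len(chosen))
        )
        workflows.append(Workflow(
            id=f"S{w_idx + 1}",
            task_instances=tuple(chosen),
            edges=edges,
            ports=(PortSpec("input", "Sequences"), PortSpec("output", "Results")),
            class_label=cls,
        ))
    return WorkflowSet(task_pool=tuple(pool_tasks), workflows=tuple(workflows))


# --------------------------------------------------------------------------
# Factorial experiments
# --------------------------------------------------------------------------


def reference_partition(ws: WorkflowSet) -> Partition:
    """Partition induced by the workflows' class labels."""
    labels = {w.id: w.class_label for w in ws.workflows}
    if any(v is None for v in labels.values()):
        raise ValueError("all workflows need a class_label")
    return labels_to_partition(labels, ws.workflow_ids)


def rand_by_task_count(ws: WorkflowSet, part: Partition,
                       ref: Partition) -> pd.DataFrame:
    """Rand index restricted to workflows of each task count (strata table)."""
    counts = {w.id: w.n_tasks for w in ws.workflows}
    rows = []
    for c in sorted(set(counts.values())):
        ids = [wid for wid in part.ids if counts[wid] == c]
        if len(ids) < 2:
            continue
        sub = lambda p: Partition(
            tuple(ids),
            _relabel(np.array([p.labels[list(p.ids).index(w)] for w in ids])))
        rows.append({"n_tasks": c, "n_workflows": len(ids),
                     "rand_index": rand_index(sub(part), sub(ref))})
    return pd.DataFrame(rows)


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, inv = np.unique(labels, return_inverse=True)
    return inv


def experiment_grid(ws: WorkflowSet,
                    encodings: Iterable[str] = ("I", "II", "III", "IV"),
                    metrics: Iterable[str] = ("euclidean",),
                    algorithms: Iterable[str] = ("kmeans",),
                    indices: Iterable[str] = ("CH",),
                    rule: KeywordRule | None = None,
                    k_min: int = 2, k_max: int | None = None,
                    n_starts: int = 100,
                    seed: int | None = None) -> pd.DataFrame:
    """Run K selection for every factor combination; tabulate the results.

    Emits one row per (encoding, metric, algorithm, index) cell with the
    selected K, the index value and — when the collection carries class
    labels — the Rand index against them. Reproducible given ``seed``.
    """
    encodings, metrics = list(encodings), list(metrics)
    algorithms, indices = list(algorithms), list(indices)
    if not (encodings and metrics and algorithms and indices):
        raise ValueError("all factor lists must be non-empty")
    ref = None
    if all(w.class_label is not None for w in ws.workflows):
        ref = reference_partition(ws)
    ss = np.random.SeedSequence(seed)
    rows = []
    cells = [(e, m, a, i) for e in encodings for m in metrics
             for a in algorithms for i in indices]
    for (etype, metric, algo, index), child in zip(cells, ss.spawn(len(cells))):
        enc = encode(ws, etype, rule)
        sel = select_k(enc, algo, metric, index, k_min=k_min, k_max=k_max,
                       n_starts=n_starts,
                       seed=int(child.generate_state(1)[0] % (2**31)))
        row = {
            "encoding": enc.encoding_type, "metric": metric,
            "algorithm": algo, "index": sel.index_name,
            "chosen_k": sel.chosen_k,
            "index_value": sel.per_k[sel.chosen_k][0],
            "objective": sel.chosen_run.objective,
        }
        if ref is not None:
            row["rand_index"] = rand_index(sel.chosen_partition, ref)
        rows.append(row)
    return pd.DataFrame(rows)
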