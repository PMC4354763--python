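"""Matrix encodings of workflow collections.

Each encoder maps a :class:`~wfclust.workflow_model.WorkflowSet` to a
variables × workflows count matrix ``W`` together with a non-negative
per-variable weight vector ``y`` (the pair the weighted distances operate on):

* **Type I** — presence/absence of task-instance slots (binary); a task used
  twice in some workflow contributes two variables, ``"Name (1)"`` and
  ``"Name (2)"``. Weights are the tasks' average execution times.
* **Type II** — occurrence counts per task type; weights come from a keyword
  rule (tasks whose name or annotations contain the keyword get
  ``match_weight``, the rest ``default_weight``).
* **Type III** — pair-of-tasks (directed edge) counts plus, for every task
  type that is terminal in at least one workflow, a singleton variable
  counting its terminal instances. Edge weights are the summed execution
  times of the two member tasks; singleton weights the task's own time.
* **Type IV** — the Type III variables re-weighted by the keyword rule, plus
  ``INPUT_<datatype>`` / ``OUTPUT_<datatype>`` port-count variables with
  weight ``match_weight``.

Variables are ordered lexicographically by name so matrices are reproducible
bit-exactly; adding a workflow only appends a column (and possibly new rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .workflow_model import Task, Workflow, WorkflowSet, terminal_tasks

__all__ = [
    "EncodingResult",
    "KeywordRule",
    "encode_type1",
    "encode_type2",
    "encode_type3",
    "encode_type4",
    "encode",
    "strip_weights",
]


@dataclass(frozen=True)
class KeywordRule:
    """Keyword-based variable weighting.

    A task *matches* if the keyword occurs as a case-insensitive substring of
    its name or of any of its annotations. Matching variables receive
    ``match_weight``, the others ``default_weight``.
    """

    keyword: str
    match_weight: float = 1.0
    default_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.match_weight < 0 or self.default_weight < 0:
            raise ValueError("keyword weights must be non-negative")

    def matches(self, task: Task) -> bool:
        kw = self.keyword.lower()
        if not kw:
            return False
        if kw in task.name.lower():
            return True
        return any(kw in a.lower() for a in task.annotations)

    def weight(self, *tasks: Task) -> float:
        return self.match_weight if any(self.matches(t) for t in tasks) else self.default_weight


@dataclass(frozen=True)
class EncodingResult:
    """A variables × workflows matrix with its per-variable weight vector."""

    encoding_type: str  # "I" | "II" | "III" | "IV"
    variables: tuple[str, ...]
    matrix: np.ndarray  # shape (n_variables, n_workflows), non-negative ints
    weights: np.ndarray  # shape (n_variables,), non-negative reals
    workflow_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "workflow_ids", tuple(self.workflow_ids))
        if m.shape != (len(self.variables), len(self.workflow_ids)):
            raise ValueError("matrix shape inconsistent with variable/workflow lists")
        if w.shape != (len(self.variables),):
            raise ValueError("weight vector length inconsistent with variables")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")
        if (m < 0).any():
            raise ValueError("matrix entries must be non-negative")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def n_workflows(self) -> int:
        return len(self.workflow_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def column(self, i: int) -> np.ndarray:
        return self.matrix[:, i]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: variable rows, workflow columns, final weight column."""
        df = pd.DataFrame(
            self.matrix.astype(int), index=list(self.variables),
            columns=list(self.workflow_ids),
        )
        df.index.name = "variable"
        df["weight"] = self.weights
        return df

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["weight"] = df["weight"].map(lambda v: f"{v:.2f}")
        df.to_csv(path)


def _result(etype: str, rows: dict[str, tuple[np.ndarray, float]],
            ws: WorkflowSet) -> EncodingResult:
    names = sorted(rows)
    matrix = np.array([rows[v][0] for v in names], dtype=float)
    weights = np.array([rows[v][1] for v in names], dtype=float)
    return EncodingResult(etype, tuple(names), matrix, weights,
                          tuple(ws.workflow_ids))


def _require_nonempty(ws: WorkflowSet) -> None:
    if not ws.workflows:
        raise ValueError("cannot encode an empty workflow collection")


def _occurrences(w: Workflow) -> dict[str, int]:
    out: dict[str, int] = {}
    for tid in w.task_instances:
        out[tid] = out.get(tid, 0) + 1
    return out


def encode_type1(ws: WorkflowSet) -> EncodingResult:
    """Presence/absence of task-instance slots, weighted by execution time.

    The k-th occurrence of a task that some workflow uses at least k ≥ 2
    times becomes its own binary variable named ``"Name (k)"``; tasks never
    repeated keep their plain name.
    """
    _require_nonempty(ws)
    occ = [_occurrences(w) for w in ws.workflows]
    max_occ = {t.id: max((o.get(t.id, 0) for o in occ), default=0)
               for t in ws.task_pool}
    rows: dict[str, tuple[np.ndarray, float]] = {}
    for t in ws.task_pool:
        if max_occ[t.id] == 0:
            continue
        for k in range(1, max_occ[t.id] + 1):
            name = t.name if max_occ[t.id] == 1 else f"{t.name} ({k})"
            row = np.array([1.0 if o.get(t.id, 0) >= k else 0.0 for o in occ])
            rows[name] = (row, t.avg_exec_time)
    return _result("I", rows, ws)


def encode_type2(ws: WorkflowSet, rule: KeywordRule) -> EncodingResult:
    """Occurrence counts per task type, keyword-weighted."""
    _require_nonempty(ws)
    occ = [_occurrences(w) for w in ws.workflows]
    rows: dict[str, tuple[np.ndarray, float]] = {}
    for t in ws.task_pool:
        row = np.array([float(o.get(t.id, 0)) for o in occ])
        if row.any():
            rows[t.name] = (row, rule.weight(t))
    return _result("II", rows, ws)


def _pair_counts(ws: WorkflowSet):
    """Edge and terminal-singleton counts per workflow.

    Returns ``(edge_rows, singleton_rows)`` where keys are (src_id, dst_id)
    task-id pairs resp. task ids, and values are per-workflow count arrays.
    """
    n = len(ws.workflows)
    edge_rows: dict[tuple[str, str], np.ndarray] = {}
    term_rows: dict[str, np.ndarray] = {}
    for j, w in enumerate(ws.workflows):
        for a, b in w.edges:
            key = (w.task_instances[a], w.task_instances[b])
            edge_rows.setdefault(key, np.zeros(n))[j] += 1
        for i in terminal_tasks(w):
            term_rows.setdefault(w.task_instances[i], np.zeros(n))[j] += 1
    return edge_rows, term_rows


def encode_type3(ws: WorkflowSet) -> EncodingResult:
    """Pair-of-tasks (directed edges) plus terminal-task singleton variables.

    Edge variables are named ``"SrcName → DstName"`` and weighted by the sum
    of the two member tasks' execution times; singleton variables count the
    terminal instances of a task type and carry that task's own time.
    """
    _require_nonempty(ws)
    edge_rows, term_rows = _pair_counts(ws)
    pool = ws.task_index
    rows: dict[str, tuple[np.ndarray, float]] = {}
    for (src, dst), row in edge_rows.items():
        name = f"{pool[src].name} → {pool[dst].name}"
        rows[name] = (row, pool[src].avg_exec_time + pool[dst].avg_exec_time)
    for tid, row in term_rows.items():
        rows[pool[tid].name] = (row, pool[tid].avg_exec_time)
    return _result("III", rows, ws)


def encode_type4(ws: WorkflowSet, rule: KeywordRule) -> EncodingResult:
    """Type III variables re-weighted by keyword, plus IO-port variables.

    A pair (or singleton) variable gets ``match_weight`` when either member
    task matches the keyword, else ``default_weight``. Port variables
    ``INPUT_<datatype>`` / ``OUTPUT_<datatype>`` count the workflow-level
    ports of each data type and always carry ``match_weight``.
    """
    _require_nonempty(ws)
    edge_rows, term_rows = _pair_counts(ws)
    pool = ws.task_index
    rows: dict[str, tuple[np.ndarray, float]] = {}
    for (src, dst), row in edge_rows.items():
        name = f"{pool[src].name} → {pool[dst].name}"
        rows[name] = (row, rule.weight(pool[src], pool[dst]))
    for tid, row in term_rows.items():
        rows[pool[tid].name] = (row, rule.weight(pool[tid]))
    n = len(ws.workflows)
    port_rows: dict[str, np.ndarray] = {}
    for j, w in enumerate(ws.workflows):
        for p in w.ports:
            name = f"{p.direction.upper()}_{p.datatype}"
            port_rows.setdefault(name, np.zeros(n))[j] += 1
    for name, row in port_rows.items():
        rows[name] = (row, rule.match_weight)
    return _result("IV", rows, ws)


def encode(ws: WorkflowSet, encoding_type: str,
           rule: KeywordRule | None = None) -> EncodingResult:
    """Dispatch by encoding type ("I".."IV" or "1".."4")."""
    etype = {"1": "I", "2": "II", "3": "III", "4": "IV"}.get(
        str(encoding_type), str(encoding_type).upper())
    if etype in ("II", "IV") and rule is None:
        raise ValueError(f"encoding Type {etype} requires a KeywordRule")
    if etype == "I":
        return encode_type1(ws)
    if etype == "II":
        return encode_type2(ws, rule)
    if etype == "III":
        return encode_type3(ws)
    if etype == "IV":
        return encode_type4(ws, rule)
    raise ValueError(f"unknown encoding type: {encoding_type!r}")


def strip_weights(enc: EncodingResult) -> EncodingResult:
    """Unweighted variant: same matrix, all weights set to 1."""
    return replace(enc, weights=np.ones(enc.n_variables))
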