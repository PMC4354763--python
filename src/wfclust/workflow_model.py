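"""Data model for collections of scientific workflows.

A workflow is a directed acyclic graph of *task instances* (the same task —
e.g. a program such as PhyML — may occur more than once in one workflow),
plus typed input/output ports describing the primary data the workflow
consumes and produces. A :class:`WorkflowSet` bundles the workflows with the
shared pool of task definitions (name, category, average execution time,
keyword annotations) that the encoders draw their weights from.

The module also ships :func:`figure1_fixture`, a small built-in collection of
five phylogenetic-analysis workflows (multiple alignment → tree inference →
horizontal-gene-transfer detection pipelines) used throughout the test suite
and documentation as a worked example.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Task",
    "PortSpec",
    "Workflow",
    "WorkflowSet",
    "WorkflowFormatError",
    "load_workflows",
    "loads_workflows",
    "save_workflows",
    "dumps_workflows",
    "load_reference_labels",
    "terminal_tasks",
    "validate_workflow",
    "figure1_fixture",
]


class WorkflowFormatError(ValueError):
    """Raised when a workflow document violates the schema or its invariants."""


@dataclass(frozen=True)
class Task:
    """A task (computational method) available to workflows.

    Parameters
    ----------
    id:
        Unique identifier within a collection's task pool.
    name:
        Display name, e.g. ``"PhyML"``. Defaults to ``id``.
    category:
        Optional grouping such as ``"alignment"`` or ``"tree-inference"``.
    avg_exec_time:
        Average execution time in arbitrary (but collection-consistent)
        units; must be non-negative. Used as the variable weight in the
        presence/absence and pair-of-tasks encodings.
    annotations:
        Keyword strings attached to the task (searched, together with the
        name, by keyword weighting rules).
    """

    id: str
    name: str = ""
    category: str | None = None
    avg_exec_time: float = 0.0
    annotations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name:
            object.__setattr__(self, "name", self.id)
        object.__setattr__(self, "annotations", frozenset(self.annotations))


@dataclass(frozen=True)
class PortSpec:
    """A workflow-level input or output port carrying a named data type."""

    direction: str  # "input" | "output"
    datatype: str

    def __post_init__(self) -> None:
        if self.direction not in ("input", "output"):
            raise WorkflowFormatError(
                f"port direction must be 'input' or 'output', got {self.direction!r}"
            )
        if not self.datatype:
            raise WorkflowFormatError("port datatype must be non-empty")


@dataclass(frozen=True)
class Workflow:
    """A single workflow: task instances, directed edges and ports.

    ``task_instances`` is an ordered list of task *ids* referring to the
    owning :class:`WorkflowSet`'s pool; the same id may appear several times.
    ``edges`` are ``(source_index, target_index)`` pairs over instance
    positions. Ports carry multiplicity by repetition (a workflow with two
    ``Tree`` inputs lists the port twice).
    """

    id: str
    task_instances: tuple[str, ...]
    edges: tuple[tuple[int, int], ...] = ()
    ports: tuple[PortSpec, ...] = ()
    class_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "task_instances", tuple(self.task_instances))
        object.__setattr__(
            self, "edges", tuple((int(a), int(b)) for a, b in self.edges)
        )
        object.__setattr__(self, "ports", tuple(self.ports))

    @property
    def n_tasks(self) -> int:
        return len(self.task_instances)

    def inputs(self) -> list[str]:
        return [p.datatype for p in self.ports if p.direction == "input"]

    def outputs(self) -> list[str]:
        return [p.datatype for p in self.ports if p.direction == "output"]

    def graph(self) -> nx.DiGraph:
        """Instance-level directed graph (nodes are instance indices)."""
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.task_instances)))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class WorkflowSet:
    """A task pool plus an ordered collection of workflows over it."""

    task_pool: tuple[Task, ...]
    workflows: tuple[Workflow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "task_pool", tuple(self.task_pool))
        object.__setattr__(self, "workflows", tuple(self.workflows))
        violations = self.validate()
        if violations:
            raise WorkflowFormatError("; ".join(violations))

    @property
    def task_index(self) -> Mapping[str, Task]:
        return {t.id: t for t in self.task_pool}

    @property
    def workflow_ids(self) -> list[str]:
        return [w.id for w in self.workflows]

    def task(self, task_id: str) -> Task:
        return self.task_index[task_id]

    def validate(self) -> list[str]:
        """All structural violations in the collection (empty list == valid)."""
        out: list[str] = []
        seen_tasks: set[str] = set()
        for t in self.task_pool:
            if t.id in seen_tasks:
                out.append(f"duplicate task id: {t.id!r}")
            seen_tasks.add(t.id)
        seen_wf: set[str] = set()
        for w in self.workflows:
            if w.id in seen_wf:
                out.append(f"duplicate workflow id: {w.id!r}")
            seen_wf.add(w.id)
            out.extend(validate_workflow(w, self.task_pool))
        return out


def validate_workflow(w: Workflow, task_pool: Sequence[Task]) -> list[str]:
    """Check one workflow's invariants; returns violation descriptions.

    Violations are returned rather than raised so callers can report all
    problems in a document at once.
    """
    out: list[str] = []
    pool = {t.id: t for t in task_pool}
    n = len(w.task_instances)
    if n == 0:
        out.append(f"workflow {w.id!r}: at least one task instance required")
    for tid in w.task_instances:
        if tid not in pool:
            out.append(f"workflow {w.id!r}: unknown task {tid!r}")
    for a, b in w.edges:
        if not (0 <= a < n and 0 <= b < n):
            out.append(
                f"workflow {w.id!r}: edge ({a}, {b}) references an invalid "
                f"instance index (valid range 0..{n - 1})"
            )
        elif a == b:
            out.append(
                f"workflow {w.id!r}: workflow is not acyclic "
                f"(self-edge at instance {a})"
            )
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from((a, b) for a, b in w.edges if 0 <= a < n and 0 <= b < n and a != b)
    if not nx.is_directed_acyclic_graph(g):
        out.append(f"workflow {w.id!r}: workflow is not acyclic")
    for tid in set(w.task_instances):
        t = pool.get(tid)
        if t is not None and t.avg_exec_time < 0:
            out.append(
                f"task {tid!r}: non-negative time violated "
                f"(avg_exec_time={t.avg_exec_time})"
            )
    return out


def terminal_tasks(w: Workflow) -> list[int]:
    """Instance indices with no outgoing edge to another task instance.

    Returned in instance-index order. Every non-empty acyclic workflow has at
    least one terminal instance. Terminal tasks supply the singleton
    variables of the pair-of-tasks encodings.
    """
    has_out = {a for a, _ in w.edges}
    return [i for i in range(len(w.task_instances)) if i not in has_out]


# --------------------------------------------------------------------------
# JSON serialization
#
# Schema (documented contract, see README):
#   {
#     "task_pool": [{"id", "name", "category", "avg_exec_time", "annotations"}],
#     "workflows": [{"id", "instances": [task_id, ...],
#                    "edges": [[src_idx, dst_idx], ...],
#                    "inputs": [datatype, ...], "outputs": [datatype, ...],
#                    "class_label"}]
#   }
# --------------------------------------------------------------------------


def _task_to_json(t: Task) -> dict:
    return {
        "id": t.id,
        "name": t.name,
        "category": t.category,
        "avg_exec_time": t.avg_exec_time,
        "annotations": sorted(t.annotations),
    }


def _workflow_to_json(w: Workflow) -> dict:
    return {
        "id": w.id,
        "instances": list(w.task_instances),
        "edges": [list(e) for e in w.edges],
        "inputs": w.inputs(),
        "outputs": w.outputs(),
        "class_label": w.class_label,
    }


def dumps_workflows(ws: WorkflowSet) -> str:
    doc = {
        "task_pool": [_task_to_json(t) for t in ws.task_pool],
        "workflows": [_workflow_to_json(w) for w in ws.workflows],
    }
    return json.dumps(doc, indent=2, sort_keys=False)


def save_workflows(ws: WorkflowSet, path: str | Path) -> None:
    Path(path).write_text(dumps_workflows(ws) + "\n")


def loads_workflows(text: str) -> WorkflowSet:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise WorkflowFormatError(f"malformed document: {exc}") from exc
    if not isinstance(doc, dict) or "task_pool" not in doc or "workflows" not in doc:
        raise WorkflowFormatError(
            "malformed document: top-level keys 'task_pool' and 'workflows' required"
        )
    try:
        tasks = tuple(
            Task(
                id=t["id"],
                name=t.get("name", t["id"]),
                category=t.get("category"),
                avg_exec_time=float(t.get("avg_exec_time", 0.0)),
                annotations=frozenset(t.get("annotations", ())),
            )
            for t in doc["task_pool"]
        )
        workflows = tuple(
            Workflow(
                id=w["id"],
                task_instances=tuple(w["instances"]),
                edges=tuple((int(a), int(b)) for a, b in w.get("edges", ())),
                ports=tuple(
                    [PortSpec("input", d) for d in w.get("inputs", ())]
                    + [PortSpec("output", d) for d in w.get("outputs", ())]
                ),
                class_label=w.get("class_label"),
            )
            for w in doc["workflows"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise WorkflowFormatError(f"malformed document: {exc}") from exc
    return WorkflowSet(task_pool=tasks, workflows=workflows)


def load_workflows(path: str | Path) -> WorkflowSet:
    """Read and validate a workflow collection from a JSON document."""
    return loads_workflows(Path(path).read_text())


def load_reference_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``workflow_id,class_label`` CSV (header required)."""
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows[0]) < 2:
        raise WorkflowFormatError("malformed document: expected a two-column CSV header")
    return {r[0]: r[1] for r in rows[1:] if r}


# --------------------------------------------------------------------------
# Built-in five-workflow example collection
# --------------------------------------------------------------------------

_FIXTURE_TIMES = {
    "Blast (NCBI)": 0.35,
    "ClustalW2": 0.49,
    "HGT Detector 3.2": 0.88,
    "Muscle": 0.41,
    "PROTML (Phylip)": 0.68,
    "PhyML": 1.13,
    "Probcons": 0.55,
    "Robinson & Foulds distance": 0.25,
    "SEQBOOT (Phylip)": 0.14,
    "Seq-Gen": 0.43,
}

_FIXTURE_CATEGORIES = {
    "Blast (NCBI)": "hgt-detection",
    "ClustalW2": "alignment",
    "HGT Detector 3.2": "hgt-detection",
    "Muscle": "alignment",
    "PROTML (Phylip)": "tree-inference",
    "PhyML": "tree-inference",
    "Probcons": "alignment",
    "Robinson & Foulds distance": "hgt-detection",
    "SEQBOOT (Phylip)": "tree-inference",
    "Seq-Gen": "simulation",
}

_STD_OUTPUTS = ("Matrix", "OutputText", "Results")


def figure1_fixture() -> WorkflowSet:
    """Five phylogenetic-analysis workflows used as the worked example.

    The collection consists of alignment → tree-inference →
    horizontal-gene-transfer-detection pipelines built from ten methods with
    known average execution times. W5 contains two instances of PhyML; W4 has
    two ``Tree`` input ports and a disconnected tree-comparison task. All
    four matrix encodings of this collection are fully determined and are
    frozen as expected values in the test suite.

    Note: one occurrence cell of the published pair-of-tasks matrix for this
    collection ("Probcons → PhyML" in W4) is inconsistent with the
    presence/absence and occurrence encodings of the same workflows; this
    fixture encodes W4 without Probcons, which is the self-consistent reading.
    """
    pool = tuple(
        Task(
            id=name,
            name=name,
            category=_FIXTURE_CATEGORIES[name],
            avg_exec_time=t,
            annotations=frozenset({"HGT", "horizontal gene transfer"})
            if name == "HGT Detector 3.2"
            else frozenset(),
        )
        for name, t in sorted(_FIXTURE_TIMES.items())
    )

    def ports(inputs: Iterable[str], outputs: Iterable[str]) -> tuple[PortSpec, ...]:
        return tuple(
            [PortSpec("input", d) for d in inputs]
            + [PortSpec("output", d) for d in outputs]
        )

    workflows = (
        Workflow(
            id="W1",
            task_instances=(
                "Muscle",
                "SEQBOOT (Phylip)",
                "PROTML (Phylip)",
                "HGT Detector 3.2",
            ),
            edges=((0, 1), (1, 2), (2, 3)),
            ports=ports(["Sequences", "Tree"], _STD_OUTPUTS),
        ),
        Workflow(
            id="W2",
            task_instances=("Seq-Gen", "ClustalW2", "PhyML", "HGT Detector 3.2"),
            edges=((0, 1), (1, 2), (2, 3)),
            ports=ports(["Tree"], _STD_OUTPUTS),
        ),
        Workflow(
            id="W3",
            task_instances=("Probcons", "PhyML", "HGT Detector 3.2"),
            edges=((0, 1), (1, 2)),
            ports=ports(["Sequences", "Tree"], _STD_OUTPUTS),
        ),
        Workflow(
            id="W4",
            task_instances=("Seq-Gen", "Blast (NCBI)", "Robinson & Foulds distance"),
            edges=((0, 1),),
            ports=ports(
                ["Tree", "Tree"],
                ["Blast (NCBI)", "Matrix", "MultipleTrees", "OutputText",
                 "OutputText", "Results"],
            ),
        ),
        Workflow(
            id="W5",
            task_instances=("Muscle", "ClustalW2", "PhyML", "PhyML",
                            "HGT Detector 3.2"),
            edges=((0, 2), (1, 3), (2, 4), (3, 4)),
            ports=ports(["Sequences"], _STD_OUTPUTS),
        ),
    )
    return WorkflowSet(task_pool=pool, workflows=workflows)
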