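"""Hierarchical classification of workflows: UPGMA, NJ, tree comparison.

Trees are :class:`dendropy.Tree` objects with leaves labelled by workflow
ids. UPGMA produces a rooted ultrametric tree (equal root-to-leaf path
lengths); neighbor joining produces an unrooted additive tree and recovers
any additive distance matrix exactly (negative branch lengths, which NJ can
produce on non-additive input, are preserved and flagged via
:func:`has_negative_lengths` rather than clamped). Merge/join ties are
broken toward the lexicographically smallest leaf pair so results are
reproducible.

Also here: the weighted least-squares fit score between a tree and a
distance matrix, multifurcating reference trees built from class labels,
Robinson–Foulds (bipartition symmetric-difference) distances, Newick I/O
and the PHYLIP square distance-matrix format.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "upgma",
    "neighbor_joining",
    "ls_fit_score",
    "reference_tree",
    "rf_distance",
    "tree_distance_matrix",
    "has_negative_lengths",
    "write_newick",
    "parse_newick",
    "read_phylip_distances",
    "write_phylip_distances",
    "NewickError",
]


class NewickError(ValueError):
    """Raised for malformed Newick text."""


def _check_square(D: DistanceMatrix, min_n: int) -> None:
    if D.n < min_n:
        raise ValueError(f"at least {min_n} elements required, got {D.n}")


def _new_tree(labels) -> tuple[dendropy.Tree, dict[str, dendropy.Node]]:
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    leaves = {}
    for lab in labels:
        node = dendropy.Node()
        node.taxon = ns.new_taxon(label=lab)
        leaves[lab] = node
    return tree, leaves


def upgma(D: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    At every step the pair of clusters at minimal average distance is
    merged (ties → the pair with the lexicographically smallest leaf
    labels); the merge node is placed at height d/2 so every root-to-leaf
    path has equal length.
    """
    _check_square(D, 2)
    tree, leaf_nodes = _new_tree(D.ids)
    # active clusters: key -> (node, size, height, min leaf label)
    active: dict[int, tuple[dendropy.Node, int, float, str]] = {
        i: (leaf_nodes[lab], 1, 0.0, lab) for i, lab in enumerate(D.ids)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D.values[i, j])
        for i in range(D.n) for j in range(i + 1, D.n)
    }
    next_key = D.n
    while len(active) > 1:
        best = None
        for (i, j), d in dist.items():
            if i not in active or j not in active:
                continue
            pair = tuple(sorted((active[i][3], active[j][3])))
            cand = (d, pair, (i, j))
            if best is None or cand[:2] < best[:2]:
                best = cand
        d, _, (i, j) = best
        node_i, n_i, h_i, lab_i = active[i]
        node_j, n_j, h_j, lab_j = active[j]
        height = d / 2.0
        parent = dendropy.Node()
        parent.add_child(node_i)
        parent.add_child(node_j)
        node_i.edge.length = height - h_i
        node_j.edge.length = height - h_j
        # size-weighted average linkage to every other active cluster
        for k in list(active):
            if k in (i, j):
                continue
            d_ik = dist[tuple(sorted((i, k)))]
            d_jk = dist[tuple(sorted((j, k)))]
            dist[tuple(sorted((next_key, k)))] = (
                (n_i * d_ik + n_j * d_jk) / (n_i + n_j))
        del active[i], active[j]
        active[next_key] = (parent, n_i + n_j, height, min(lab_i, lab_j))
        next_key += 1
    (root, _, _, _), = active.values()
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; exact on additive distances.

    The pair minimizing the rate-corrected criterion
    Q(i, j) = (N − 2) d(i, j) − r_i − r_j is joined at each step (ties →
    lexicographically smallest leaf pair); the returned tree is unrooted
    (trifurcating seed node).
    """
    _check_square(D, 3)
    tree, leaf_nodes = _new_tree(D.ids)
    nodes = {i: leaf_nodes[lab] for i, lab in enumerate(D.ids)}
    minlab = {i: lab for i, lab in enumerate(D.ids)}
    d = {
        tuple(sorted((i, j))): float(D.values[i, j])
        for i in range(D.n) for j in range(i + 1, D.n)
    }
    active = set(range(D.n))
    next_key = D.n

    def dd(i: int, j: int) -> float:
        return 0.0 if i == j else d[tuple(sorted((i, j)))]

    while len(active) > 3:
        N = len(active)
        r = {i: sum(dd(i, k) for k in active) for i in active}
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                q = (N - 2) * dd(i, j) - r[i] - r[j]
                pair = tuple(sorted((minlab[i], minlab[j])))
                cand = (q, pair, (i, j))
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, (i, j) = best
        li = dd(i, j) / 2.0 + (r[i] - r[j]) / (2.0 * (N - 2))
        lj = dd(i, j) - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        for k in active - {i, j}:
            d[tuple(sorted((next_key, k)))] = (dd(i, k) + dd(j, k) - dd(i, j)) / 2.0
        active -= {i, j}
        nodes[next_key] = parent
        minlab[next_key] = min(minlab[i], minlab[j])
        active.add(next_key)
        next_key += 1
    # join the last three clusters at a central (unrooted) node
    i, j, k = sorted(active, key=lambda a: minlab[a])
    center = dendropy.Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        center.add_child(nodes[a])
        nodes[a].edge.length = (dd(a, b) + dd(a, c) - dd(b, c)) / 2.0
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def has_negative_lengths(tree: dendropy.Tree, tol: float = 1e-12) -> bool:
    """True if any edge of the tree has a negative branch length."""
    return any(
        e.length is not None and e.length < -tol
        for e in tree.preorder_edge_iter()
    )


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    M = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            M[a, b] = M[b, a] = pdm.patristic_distance(taxa[a], taxa[b])
    return DistanceMatrix(tuple(t.label for t in taxa), M, "tree")


def ls_fit_score(tree: dendropy.Tree, D: DistanceMatrix, p: float = 2.0) -> float:
    """Weighted least-squares fit Σ_{i<j} (δ_ij − d_ij)² / d_ij^p.

    δ is the tree path length, d the observed distance; p = 2 is the
    Felsenstein weighting, p = 0 plain (unweighted) least squares. The score
    is 0 iff the tree's path lengths reproduce D exactly.
    """
    td = tree_distance_matrix(tree)
    if set(td.ids) != set(D.ids):
        raise ValueError("tree leaves do not match the distance matrix ids")
    pos = {lab: i for i, lab in enumerate(D.ids)}
    total = 0.0
    for a in range(td.n):
        for b in range(a + 1, td.n):
            dij = float(D.values[pos[td.ids[a]], pos[td.ids[b]]])
            if dij <= 0.0 and p > 0:
                raise ValueError(
                    f"undefined weight: zero distance between {td.ids[a]!r} "
                    f"and {td.ids[b]!r} with p={p}")
            total += (td.values[a, b] - dij) ** 2 / (dij ** p if p else 1.0)
    return float(total)


def reference_tree(labels: dict[str, str]) -> dendropy.Tree:
    """Multifurcating reference tree from id → class labels.

    The root has one child per class and each class node's children are its
    member leaves; all edges have unit length (only the topology matters for
    Robinson–Foulds comparisons).
    """
    by_class: dict[str, list[str]] = {}
    for wid, cls in labels.items():
        by_class.setdefault(str(cls), []).append(wid)
    if len(by_class) < 2:
        raise ValueError("at least 2 classes are required for a reference tree")
    for cls, members in by_class.items():
        if not members:
            raise ValueError(f"class {cls!r} has no members")
    tree, leaf_nodes = _new_tree(sorted(labels))
    root = dendropy.Node()
    for cls in sorted(by_class):
        members = sorted(by_class[cls])
        if len(members) == 1:
            child = leaf_nodes[members[0]]
        else:
            child = dendropy.Node()
            for wid in members:
                child.add_child(leaf_nodes[wid])
                leaf_nodes[wid].edge.length = 1.0
        root.add_child(child)
        child.edge.length = 1.0
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to one-line Newick with branch lengths."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_newick(text: str) -> dendropy.Tree:
    """Parse Newick text (multifurcations allowed)."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return tree


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance: bipartitions present in exactly one tree.

    Both trees are treated as unrooted; only non-trivial bipartitions count.
    The trees must share an identical leaf-label set.
    """
    labels1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    labels2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if labels1 != labels2:
        raise ValueError("trees must have identical leaf sets")
    # re-read through newick into one shared namespace for comparison
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                          taxon_namespace=ns)
    b = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                          taxon_namespace=ns)
    for t in (a, b):
        t.is_rooted = False
        t.update_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


# --------------------------------------------------------------------------
# PHYLIP square distance matrix format
# --------------------------------------------------------------------------


def write_phylip_distances(D: DistanceMatrix, path: str | Path) -> None:
    """Write a PHYLIP square distance matrix (names padded to 10 chars)."""
    lines = [f"    {D.n}"]
    for i, lab in enumerate(D.ids):
        name = lab[:10].ljust(10)
        vals = "  ".join(f"{v:.6f}" for v in D.values[i])
        lines.append(f"{name}{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip_distances(path: str | Path,
                          metric_tag: str = "euclidean") -> DistanceMatrix:
    """Read a PHYLIP square distance matrix."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed PHYLIP matrix: {exc}") from exc
    if len(lines) != n + 1:
        raise ValueError(
            f"malformed PHYLIP matrix: expected {n} rows, got {len(lines) - 1}")
    ids, rows = [], []
    for ln in lines[1:]:
        name = ln[:10].strip()
        vals = [float(v) for v in ln[10:].split()]
        if len(vals) != n:
            raise ValueError(
                f"malformed PHYLIP matrix: row {name!r} has {len(vals)} values")
        ids.append(name)
        rows.append(vals)
    return DistanceMatrix(tuple(ids), np.array(rows), metric_tag)
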