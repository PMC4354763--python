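"""Tree building and comparison: UPGMA/NJ exactness, least-squares fit,
reference trees, Robinson-Foulds counting and Newick/PHYLIP round-trips."""

import numpy as np
import pytest

from wfclust import (
    DistanceMatrix, NewickError, has_negative_lengths, ls_fit_score,
    neighbor_joining, parse_newick, rf_distance, read_phylip_distances,
    reference_tree, tree_distance_matrix, upgma, write_newick,
    write_phylip_distances,
)


def dm(ids, rows):
    return DistanceMatrix(tuple(ids), np.asarray(rows, dtype=float))


def random_ultrametric(n, rng):
    """Random ultrametric via single random merges at increasing heights."""
    ids = [f"L{i}" for i in range(n)]
    heights = np.zeros((n, n))
    clusters = [[i] for i in range(n)]
    h = 0.0
    while len(clusters) > 1:
        h += float(rng.uniform(0.5, 2.0))
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                heights[a, b] = heights[b, a] = 2 * h
        clusters[i] = clusters[i] + clusters.pop(j)
    return dm(ids, heights)


def random_additive(n, rng):
    """Random additive matrix from a random binary tree with random lengths."""
    import dendropy
    taxa = dendropy.TaxonNamespace([f"L{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=1,
        rng=__import__("random").Random(int(rng.integers(1 << 30))))
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.2, 2.0))
    pdm = tree.phylogenetic_distance_matrix()
    taxa_sorted = sorted(taxa, key=lambda t: t.label)
    M = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            M[a, b] = M[b, a] = pdm.patristic_distance(
                taxa_sorted[a], taxa_sorted[b])
    return dm([t.label for t in taxa_sorted], M)


class TestUPGMA:
    def test_three_leaf_hand_case(self):
        D = dm("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = upgma(D)
        td = tree_distance_matrix(tree)
        assert td.ids == ("A", "B", "C")
        assert np.allclose(td.values, D.values)
        # cherry (A,B) at height 1, C attached at height 2
        assert write_newick(tree) == "(C:2.0,(A:1.0,B:1.0):1.0);"

    def test_two_leaves_half_distance_each(self):
        tree = upgma(dm("AB", [[0, 3], [3, 0]]))
        td = tree_distance_matrix(tree)
        assert td.values[0, 1] == pytest.approx(3.0)

    @pytest.mark.parametrize("n, seed", [(5, 0), (8, 1), (10, 2)])
    def test_recovers_random_ultrametrics_exactly(self, n, seed):
        D = random_ultrametric(n, np.random.default_rng(seed))
        tree = upgma(D)
        td = tree_distance_matrix(tree)
        order = [td.ids.index(i) for i in D.ids]
        assert np.allclose(td.values[np.ix_(order, order)], D.values,
                           atol=1e-9)

    def test_ultrametric_output(self):
        rng = np.random.default_rng(3)
        X = rng.random((6, 4))
        M = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        tree = upgma(dm([f"L{i}" for i in range(6)], M))
        depths = {}
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths[leaf.taxon.label] = d
        vals = list(depths.values())
        assert max(vals) - min(vals) < 1e-9


class TestNeighborJoining:
    def test_recovers_known_four_leaf_tree(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive distances
        D = dm("ABCD", [[0, 3, 8, 9], [3, 0, 9, 10],
                        [8, 9, 0, 9], [9, 10, 9, 0]])
        tree = neighbor_joining(D)
        td = tree_distance_matrix(tree)
        order = [td.ids.index(i) for i in D.ids]
        assert np.allclose(td.values[np.ix_(order, order)], D.values,
                           atol=1e-9)

    @pytest.mark.parametrize("n, seed", [(6, 0), (8, 1), (10, 2)])
    def test_recovers_random_additive_matrices(self, n, seed):
        D = random_additive(n, np.random.default_rng(seed))
        tree = neighbor_joining(D)
        td = tree_distance_matrix(tree)
        order = [td.ids.index(i) for i in D.ids]
        assert np.allclose(td.values[np.ix_(order, order)], D.values,
                           atol=1e-8)
        assert ls_fit_score(tree, D) == pytest.approx(0.0, abs=1e-12)

    def test_star_input_zero_internal_branch(self):
        D = dm("ABCD", (np.ones((4, 4)) - np.eye(4)) * 2)
        tree = neighbor_joining(D)
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.head_node and not e.head_node.is_leaf()
                    and e.length is not None]
        assert all(abs(l) < 1e-9 for l in internal)

    def test_requires_three_leaves(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm("AB", [[0, 1], [1, 0]]))

    def test_negative_lengths_flagged_not_clamped(self):
        # strongly non-additive input can force negative NJ branches
        D = dm("ABCD", [[0, 1, 9, 9], [1, 0, 1, 9],
                        [9, 1, 0, 1], [9, 9, 1, 0]])
        tree = neighbor_joining(D)
        assert isinstance(has_negative_lengths(tree), bool)


class TestLSFit:
    def test_zero_iff_exact(self):
        D = dm("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = upgma(D)
        assert ls_fit_score(tree, D) == 0.0
        D2 = dm("ABC", [[0, 2.5, 4], [2.5, 0, 4], [4, 4, 0]])
        assert ls_fit_score(tree, D2) > 0.0

    def test_single_pair_formula(self):
        tree = upgma(dm("AB", [[0, 2], [2, 0]]))  # path length 2
        D = dm("AB", [[0, 1], [1, 0]])
        assert ls_fit_score(tree, D, p=2) == pytest.approx(1.0)

    def test_p0_is_unweighted_least_squares(self):
        rng = np.random.default_rng(4)
        D = random_ultrametric(5, rng)
        noisy = DistanceMatrix(
            D.ids, D.values + (1 - np.eye(5)) * 0.1, D.metric_tag)
        tree = upgma(D)
        td = tree_distance_matrix(tree)
        order = [td.ids.index(i) for i in noisy.ids]
        delta = td.values[np.ix_(order, order)]
        expect = sum(
            (delta[i, j] - noisy.values[i, j]) ** 2
            for i in range(5) for j in range(i + 1, 5))
        assert ls_fit_score(tree, noisy, p=0) == pytest.approx(expect)

    def test_zero_distance_with_positive_p_rejected(self):
        tree = upgma(dm("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        D = dm("ABC", [[0, 0, 4], [0, 0, 4], [4, 4, 0]])
        with pytest.raises(ValueError, match="undefined weight"):
            ls_fit_score(tree, D, p=2)


class TestReferenceTree:
    def test_four_class_root_degree(self):
        labels = {f"w{i}": f"c{i % 4}" for i in range(12)}
        tree = reference_tree(labels)
        assert len(tree.seed_node.child_nodes()) == 4

    def test_all_singleton_classes_star(self):
        labels = {f"w{i}": f"c{i}" for i in range(5)}
        tree = reference_tree(labels)
        assert all(c.is_leaf() for c in tree.seed_node.child_nodes())

    def test_self_rf_zero(self):
        labels = {f"w{i}": f"c{i % 3}" for i in range(9)}
        assert rf_distance(reference_tree(labels), reference_tree(labels)) == 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2 classes"):
            reference_tree({"a": "x", "b": "x"})


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_distance(t, t) == 0

    def test_resolved_vs_star(self):
        a = parse_newick("((A,B),(C,D));")
        star = parse_newick("(A,B,C,D);")
        assert rf_distance(a, star) == 1

    def test_conflicting_quartets(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));")
        assert rf_distance(a, b) == 2

    def test_max_value_binary_trees(self):
        a = parse_newick("(((A,B),C),(D,E));")
        b = parse_newick("(((A,D),E),(B,C));")
        assert rf_distance(a, b) <= 2 * (5 - 3)

    def test_mismatched_leaves_rejected(self):
        a = parse_newick("((A,B),C);")
        b = parse_newick("((A,B),D);")
        with pytest.raises(ValueError, match="identical leaf sets"):
            rf_distance(a, b)


class TestNewickIO:
    def test_round_trip(self):
        text = "((A:1.0,B:1.0):1.0,C:2.0);"
        tree = parse_newick(text)
        again = parse_newick(write_newick(tree))
        assert rf_distance(tree, again) == 0

    def test_multifurcation_round_trip(self):
        tree = reference_tree({f"w{i}": f"c{i % 3}" for i in range(9)})
        again = parse_newick(write_newick(tree))
        assert rf_distance(tree, again) == 0

    def test_malformed_input_rejected(self):
        with pytest.raises(NewickError, match="malformed"):
            parse_newick("((A,B,(C;")


class TestPhylipIO:
    def test_round_trip(self, tmp_path):
        D = dm("ABCD", [[0, 3, 8, 9], [3, 0, 9, 10],
                        [8, 9, 0, 9], [9, 10, 9, 0]])
        path = tmp_path / "dist.phy"
        write_phylip_distances(D, path)
        D2 = read_phylip_distances(path)
        assert D2.ids == D.ids
        assert np.allclose(D2.values, D.values)

    def test_malformed_rejected(self, tmp_path):
        path = tmp_path / "bad.phy"
        path.write_text("    2\nA         0.0\n")
        with pytest.raises(ValueError, match="malformed PHYLIP"):
            read_phylip_distances(path)
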