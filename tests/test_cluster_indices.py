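"""Validity indices: hand-computed values, brute-force oracles,
relabeling invariance and the K-selection rules."""

import math

import numpy as np
import pytest

from wfclust import (
    ClusterRun, DegenerateClusteringError, Partition, ch_index,
    distance_matrix, encode, kmeans_weighted, logss_choose_k, logss_index,
    select_k, silhouette_index,
)
from test_partitioning import enc_1d, FOUR_POINTS, all_partitions


def run_for(enc, labels, metric="euclidean"):
    """Wrap a fixed labelling as a converged k-means run (true centroids)."""
    labels = np.asarray(labels)
    X = enc.matrix.T
    C = np.array([X[labels == k].mean(axis=0) for k in range(labels.max() + 1)])
    return ClusterRun(Partition(enc.workflow_ids, labels), float("nan"),
                      C, "kmeans", metric, 1)


class TestCalinskiHarabasz:
    def test_two_pair_hand_value(self):
        # SS_B: centroids ±5.05 -> 2·2·5.05² = 102.01... with grand mean 5.05:
        # each pair centroid offset 5.0 -> SS_B = 4·25 = 100, SS_W = 4·0.05² = 0.01
        run = run_for(FOUR_POINTS, [0, 0, 1, 1])
        assert ch_index(FOUR_POINTS, run) == pytest.approx(20000.0)

    def test_relabeling_invariance(self, fixture_ws):
        enc = encode(fixture_ws, "I")
        a = run_for(enc, [0, 1, 1, 2, 1])
        b = run_for(enc, [2, 0, 0, 1, 0])
        assert ch_index(enc, a) == pytest.approx(ch_index(enc, b))

    @pytest.mark.parametrize("metric", ["euclidean", "cosine"])
    def test_matches_bruteforce_formula(self, fixture_ws, metric):
        """CH equals a from-scratch evaluation of its defining sums."""
        from wfclust.distances import cosine_matrix, euclidean_matrix

        enc = encode(fixture_ws, "I")
        labels = np.array([0, 1, 1, 2, 1])
        run = run_for(enc, labels, metric)
        X, w = enc.matrix.T, enc.weights
        C = run.centers
        grand = X.mean(axis=0)

        def sqdist(a, b):
            if metric == "euclidean":
                return float(np.sum(w * (a - b) ** 2))
            stack = np.vstack([a, b])
            return float(cosine_matrix(stack, w)[0, 1] ** 2)

        ssw = sum(sqdist(X[i], C[labels[i]]) for i in range(5))
        ssb = sum((labels == k).sum() * sqdist(C[k], grand) for k in range(3))
        expect = ssb / ssw * (5 - 3) / (3 - 1)
        assert ch_index(enc, run, metric) == pytest.approx(expect)

    def test_degenerate_zero_within_variance(self):
        enc = enc_1d([1.0, 1.0, 5.0, 5.0])
        run = run_for(enc, [0, 0, 1, 1])
        with pytest.raises(DegenerateClusteringError, match="zero within-cluster"):
            ch_index(enc, run)

    def test_k_out_of_range(self):
        run = run_for(FOUR_POINTS, [0, 1, 2, 3])  # K = n
        with pytest.raises(DegenerateClusteringError):
            ch_index(FOUR_POINTS, run)


class TestLogSS:
    def test_hand_value(self):
        run = run_for(FOUR_POINTS, [0, 0, 1, 1])
        assert logss_index(FOUR_POINTS, run) == pytest.approx(
            math.log(100 / 0.01), abs=1e-9)

    def test_chooser_minimizes_consecutive_difference(self):
        assert logss_choose_k({2: 1.0, 3: 3.0, 4: 3.1}) == 3

    def test_chooser_tie_returns_smaller_k(self):
        assert logss_choose_k({2: 1.0, 3: 2.0, 4: 3.0}) == 2

    def test_chooser_signed_vs_absolute(self):
        vals = {2: 5.0, 3: 1.0, 4: 1.05}
        assert logss_choose_k(vals) == 2              # signed: -4 smallest
        assert logss_choose_k(vals, absolute=True) == 3


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        # a = 0.1 for every point; b = 10.05 (outer points) / 9.95 (inner)
        part = Partition(FOUR_POINTS.workflow_ids, np.array([0, 0, 1, 1]))
        expect = ((10.05 - 0.1) / 10.05 + (9.95 - 0.1) / 9.95) / 2
        got = silhouette_index(FOUR_POINTS, part)
        assert got == pytest.approx(expect, abs=1e-9)
        assert got == pytest.approx(0.99, abs=1e-4)

    def test_identical_points_degenerate_zero(self):
        enc = enc_1d([2.0, 2.0, 2.0, 2.0])
        part = Partition(enc.workflow_ids, np.array([0, 0, 1, 1]))
        assert silhouette_index(enc, part) == 0.0

    def test_matches_bruteforce_loop(self, fixture_ws):
        enc = encode(fixture_ws, "I")
        D = distance_matrix(enc, "euclidean").values
        labels = np.array([0, 1, 1, 2, 1])
        part = Partition(enc.workflow_ids, labels)
        s = np.zeros(5)
        for i in range(5):
            own = [j for j in range(5) if labels[j] == labels[i] and j != i]
            if own:
                a = np.mean([D[i, j] for j in own])
                b = min(
                    np.mean([D[i, j] for j in range(5) if labels[j] == c])
                    for c in range(3) if c != labels[i])
                s[i] = (b - a) / max(a, b)
        expect = np.mean([s[labels == k].mean() for k in range(3)])
        assert silhouette_index(enc, part) == pytest.approx(expect)

    def test_macro_vs_per_point_variants(self, fixture_ws):
        enc = encode(fixture_ws, "I")
        part = Partition(enc.workflow_ids, np.array([0, 1, 1, 0, 1]))
        macro = silhouette_index(enc, part)
        per_point = silhouette_index(enc, part, per_point=True)
        assert macro != pytest.approx(per_point)  # unequal cluster sizes

    def test_range_bounds(self, fixture_ws):
        enc = encode(fixture_ws, "III")
        for labels in ([0, 0, 1, 1, 1], [0, 1, 2, 3, 0], [0, 1, 0, 1, 2]):
            s = silhouette_index(enc, Partition(enc.workflow_ids,
                                                np.array(labels)))
            assert -1.0 <= s <= 1.0

    def test_relabeling_and_reordering_invariance(self, fixture_ws):
        enc = encode(fixture_ws, "I")
        a = silhouette_index(enc, Partition(enc.workflow_ids,
                                            np.array([0, 1, 1, 2, 1])))
        b = silhouette_index(enc, Partition(enc.workflow_ids,
                                            np.array([1, 2, 2, 0, 2])))
        assert a == pytest.approx(b)


class TestSelectK:
    def test_two_pair_data_selects_two(self):
        sel = select_k(FOUR_POINTS, "kmeans", "euclidean", "CH",
                       k_min=2, k_max=3, n_starts=30, seed=0)
        assert sel.chosen_k == 2
        groups = {tuple(sorted(c)) for c in sel.chosen_partition.clusters()}
        assert groups == {("w0", "w1"), ("w2", "w3")}

    def test_ssw_decreases_with_k(self, fixture_ws):
        enc = encode(fixture_ws, "III")
        sel = select_k(enc, "kmeans", "euclidean", "CH", 2, 4,
                       n_starts=100, seed=1)
        ssw = [sel.ss_w[k] for k in sorted(sel.ss_w)]
        assert all(a >= b - 1e-9 for a, b in zip(ssw, ssw[1:]))

    def test_deterministic_given_seed(self, fixture_ws):
        enc = encode(fixture_ws, "I")
        a = select_k(enc, "kmeans", "cosine", "SI", 2, 4, n_starts=20, seed=9)
        b = select_k(enc, "kmeans", "cosine", "SI", 2, 4, n_starts=20, seed=9)
        assert a.chosen_k == b.chosen_k
        assert np.array_equal(a.chosen_partition.labels,
                              b.chosen_partition.labels)

    def test_invalid_scan_range(self, fixture_ws):
        enc = encode(fixture_ws, "I")
        with pytest.raises(ValueError, match="scan range"):
            select_k(enc, k_min=3, k_max=2)
        with pytest.raises(ValueError, match="scan range"):
            select_k(enc, k_min=2, k_max=5)  # n-1 = 4

    def test_perfectly_separated_duplicates_prefer_smallest_k(self):
        # 4 distinct values duplicated: SS_W = 0 from K=4 on; ties -> K=4
        enc = enc_1d([0, 0, 5, 5, 10, 10, 15, 15.])
        sel = select_k(enc, "kmeans", "euclidean", "CH", 2, 7,
                       n_starts=60, seed=2)
        assert sel.chosen_k == 4

    def test_all_indices_run(self, fixture_ws):
        enc = encode(fixture_ws, "I")
        for index in ("CH", "SI", "logSS"):
            sel = select_k(enc, "kmeans", "euclidean", index, 2, 4,
                           n_starts=50, seed=4)
            assert 2 <= sel.chosen_k <= 4
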