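import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.spatial.distance import cdist

from conemosaic.matching import (
    InsufficientPointsError,
    PairMatch,
    ThresholdStats,
    cluster_multigrader,
    confusion_from_clusters,
    confusion_from_match,
    match_pairwise,
    match_threshold,
)
from conftest import make_points, random_mosaic


def max_cardinality_tp(gt, comp, threshold):
    """Independent oracle: maximum-cardinality matching of the bipartite
    threshold graph (Hopcroft–Karp via scipy.csgraph)."""
    adj = (cdist(gt, comp) <= threshold).astype(int)
    if adj.sum() == 0:
        return 0
    m = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    return int((m != -1).sum())


class TestMatchThreshold:
    def test_worked_example(self):
        ts = match_threshold([(0, 0), (10, 0), (1, 0), (15, 0)])
        # NN distances [1, 5, 1, 5]: mean 3, sample SD 2.3094
        assert ts.mean_nn_um == pytest.approx(3.0)
        assert ts.sd_nn_um == pytest.approx(2.3094010767585, rel=1e-10)
        assert ts.threshold_um == pytest.approx(7.6188021535170, rel=1e-10)

    def test_coincident_pair_degenerates_to_zero(self):
        ts = match_threshold([(5, 5), (5, 5)])
        assert ts.mean_nn_um == 0 and ts.sd_nn_um == 0 and ts.threshold_um == 0

    def test_uniform_grid_has_zero_sd(self):
        ts = match_threshold([(i, 0) for i in range(10)])
        assert ts.mean_nn_um == pytest.approx(1.0)
        assert ts.sd_nn_um == pytest.approx(0.0, abs=1e-12)
        assert ts.threshold_um == pytest.approx(1.0)

    def test_rejects_single_point(self):
        with pytest.raises(InsufficientPointsError):
            match_threshold([(0, 0)])


class TestMatchPairwise:
    def test_worked_example_continues_to_perfect_dice(self, roi):
        master = [(0, 0), (10, 0), (1, 0), (15, 0)]
        ts = match_threshold(master)
        gt = make_points(roi, [(0, 0), (10, 0)], "A")
        comp = make_points(roi, [(1, 0), (15, 0)], "B")
        m = match_pairwise(gt, comp, ts)
        assert m.matched_pairs == [(0, 0, 1.0), (1, 1, 5.0)]
        assert m.unmatched_gt == [] and m.unmatched_comp == []

    def test_identical_sets_match_at_distance_zero(self, roi):
        pts = [(3, 4), (50, 60), (90, 10)]
        m = match_pairwise(
            make_points(roi, pts, "A"),
            make_points(roi, pts, "B"),
            ThresholdStats(0.0, 0.0, 0.0),
        )
        c = confusion_from_match(m)
        assert c.n_tp == 3 and c.n_fp == 0 and c.n_fn == 0
        assert all(d == 0 for _, _, d in m.matched_pairs)

    def test_closer_cone_wins(self, roi):
        gt = make_points(roi, [(0, 0)], "A")
        comp = make_points(roi, [(5, 0), (6, 0)], "B")
        m = match_pairwise(gt, comp, ThresholdStats(3.0, 2.0, 7.0))
        assert m.matched_pairs == [(0, 0, 5.0)]
        assert m.unmatched_comp == [1]

    def test_rejects_mismatched_rois(self, roi):
        from dataclasses import replace

        other = replace(roi, roi_id="S01_R02")
        with pytest.raises(ValueError, match="different ROIs"):
            match_pairwise(
                make_points(roi, [(0, 0)], "A"),
                make_points(other, [(0, 0)], "B"),
                ThresholdStats(0, 0, 0),
            )

    def test_conservation_and_one_to_one_on_random_inputs(self, roi):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_a, n_b = rng.integers(1, 30, size=2)
            gt = make_points(roi, rng.uniform(0, 100, (n_a, 2)), "A")
            comp = make_points(roi, rng.uniform(0, 100, (n_b, 2)), "B")
            thr = ThresholdStats(5.0, 2.0, float(rng.uniform(0, 20)))
            m = match_pairwise(gt, comp, thr)
            c = confusion_from_match(m)
            assert c.n_comp == c.n_tp + c.n_fp == n_b
            assert c.n_gt == c.n_tp + c.n_fn == n_a
            gts = [i for i, _, _ in m.matched_pairs]
            comps = [j for _, j, _ in m.matched_pairs]
            assert len(set(gts)) == len(gts) and len(set(comps)) == len(comps)
            assert all(d <= thr.threshold_um for _, _, d in m.matched_pairs)

    def test_direction_symmetric_tp_count(self, roi):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = make_points(roi, rng.uniform(0, 100, (rng.integers(1, 25), 2)), "A")
            b = make_points(roi, rng.uniform(0, 100, (rng.integers(1, 25), 2)), "B")
            thr = ThresholdStats(5, 2, float(rng.uniform(1, 15)))
            tp_ab = len(match_pairwise(a, b, thr).matched_pairs)
            tp_ba = len(match_pairwise(b, a, thr).matched_pairs)
            assert tp_ab == tp_ba

    def test_tp_monotone_in_threshold(self, roi):
        rng = np.random.default_rng(13)
        a = make_points(roi, rng.uniform(0, 100, (20, 2)), "A")
        b = make_points(roi, rng.uniform(0, 100, (20, 2)), "B")
        tps = [
            len(match_pairwise(a, b, ThresholdStats(0, 0, t)).matched_pairs)
            for t in np.linspace(0, 30, 16)
        ]
        assert tps == sorted(tps)

    def test_greedy_matches_maximum_cardinality_on_separated_mosaics(self, roi):
        """On well-separated mosaics the greedy matching attains the
        maximum-cardinality matching of the threshold graph."""
        rng = np.random.default_rng(17)
        disagreements = 0
        for _ in range(200):
            base = random_mosaic(rng, 8, 100, 100, min_sep=12.0)
            a = base[rng.random(len(base)) > 0.2]
            b = base[rng.random(len(base)) > 0.2]
            if len(a) == 0 or len(b) == 0:
                continue
            b = b + rng.normal(0, 1.0, size=b.shape)
            thr = 4.0
            m = match_pairwise(
                make_points(roi, a, "A"),
                make_points(roi, b, "B"),
                ThresholdStats(0, 0, thr),
            )
            if len(m.matched_pairs) != max_cardinality_tp(a, b, thr):
                disagreements += 1
        assert disagreements == 0


class TestClustering:
    def test_identical_annotator_trio(self, roi):
        pts = [(10, 10), (30, 30), (50, 50), (70, 70), (90, 90)]
        sets = [make_points(roi, pts, lab) for lab in ("A", "B", "C")]
        cs = cluster_multigrader(sets, ThresholdStats(0, 0, 1.0))
        assert len(cs.clusters) == 5
        assert all(set(c) == {"A", "B", "C"} for c in cs.clusters)

    def test_distant_annotator_stays_singleton(self, roi):
        sets = [
            make_points(roi, [(0, 0)], "A"),
            make_points(roi, [(1, 0)], "B"),
            make_points(roi, [(100, 100)], "C"),
        ]
        cs = cluster_multigrader(sets, ThresholdStats(0, 0, 50.0))
        groups = [set(c) for c in cs.clusters]
        assert {"A", "B"} in groups and {"C"} in groups

    def test_one_selection_per_annotator_constraint(self, roi):
        # B's point is equidistant from both of A's; it may join only one.
        sets = [
            make_points(roi, [(0, 0), (2, 0)], "A"),
            make_points(roi, [(1, 0)], "B"),
        ]
        cs = cluster_multigrader(sets)
        joined = [c for c in cs.clusters if "B" in c]
        assert len(joined) == 1
        assert joined[0] == {"A": 0, "B": 0}
        assert {"A": 1} in cs.clusters

    def test_requires_two_annotators(self, roi):
        with pytest.raises(ValueError, match="2 annotators"):
            cluster_multigrader([make_points(roi, [(0, 0)], "A")])

    def test_every_point_in_exactly_one_cluster(self, roi):
        rng = np.random.default_rng(23)
        sets = [
            make_points(roi, rng.uniform(0, 100, (rng.integers(3, 20), 2)), lab)
            for lab in ("A", "B", "C")
        ]
        cs = cluster_multigrader(sets)
        for s in sets:
            seen = [c[s.annotator] for c in cs.clusters if s.annotator in c]
            assert sorted(seen) == list(range(len(s)))

    def test_two_annotator_clustering_equals_pairwise(self, roi):
        rng = np.random.default_rng(29)
        for _ in range(30):
            base = random_mosaic(rng, 25, 100, 100, min_sep=8.0)
            a = base[rng.random(len(base)) > 0.1]
            b = base[rng.random(len(base)) > 0.1]
            b = b + rng.normal(0, 0.8, size=b.shape)
            if len(a) < 2 or len(b) < 2:
                continue
            sa = make_points(roi, a, "A")
            sb = make_points(roi, b, "B")
            cs = cluster_multigrader([sa, sb])
            cc = confusion_from_clusters(cs, "A", "B")
            cm = confusion_from_match(match_pairwise(sa, sb, cs.threshold))
            assert (cc.n_tp, cc.n_fp, cc.n_fn) == (cm.n_tp, cm.n_fp, cm.n_fn)


class TestConfusionCounts:
    def test_from_match_counts(self):
        m = PairMatch(
            threshold=ThresholdStats(0, 0, 5),
            matched_pairs=[(i, i, 1.0) for i in range(8)],
            unmatched_gt=[8, 9],
            unmatched_comp=[8, 9, 10],
            n_gt=10,
            n_comp=11,
        )
        c = confusion_from_match(m)
        assert (c.n_tp, c.n_fp, c.n_fn, c.n_gt, c.n_comp) == (8, 3, 2, 10, 11)

    def test_empty_comparison_is_all_false_negatives(self, roi):
        gt = make_points(roi, [(i * 10, 5) for i in range(5)], "A")
        comp = make_points(roi, np.empty((0, 2)), "B")
        c = confusion_from_match(match_pairwise(gt, comp, ThresholdStats(0, 0, 5)))
        assert (c.n_tp, c.n_fp, c.n_fn, c.n_gt, c.n_comp) == (0, 0, 5, 5, 0)

    def test_from_clusters_counting_and_rotation(self, roi):
        from conemosaic.matching import ClusterSet

        cs = ClusterSet(
            graders=["A", "B"],
            clusters=[{"A": 0, "B": 0}, {"A": 1}, {"B": 1}, {"A": 2, "B": 2}],
            threshold=ThresholdStats(0, 0, 1),
        )
        c_ab = confusion_from_clusters(cs, "A", "B")
        assert (c_ab.n_tp, c_ab.n_fp, c_ab.n_fn) == (2, 1, 1)
        c_ba = confusion_from_clusters(cs, "B", "A")
        assert (c_ba.n_tp, c_ba.n_fp, c_ba.n_fn) == (2, 1, 1)

    def test_unknown_annotator_rejected(self, roi):
        from conemosaic.matching import ClusterSet

        cs = ClusterSet(["A", "B"], [{"A": 0}], ThresholdStats(0, 0, 1))
        with pytest.raises(ValueError, match="unknown annotator"):
            confusion_from_clusters(cs, "A", "Z")
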