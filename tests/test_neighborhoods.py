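"""Neighborhood detection, features, k-selection, and rule classifiers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lnspatial.core import CohortTable, FrameMeta, Mode, Outcome
from lnspatial.density import InferenceError
from lnspatial.neighborhoods import (
    FEATURE_NAMES,
    NeighborhoodParams,
    RuleThresholds,
    classify_rule_based,
    detect_neighborhoods,
    kmeans_neighborhood_classes,
    loo_feature_tests,
    neighborhood_features,
    neighborhood_prevalence,
    select_k_bootstrap_wcss,
    top_features,
)
from lnspatial.synth import ARCHETYPES, sample_archetype_features

from conftest import make_map


def eps_graph_components(xy: np.ndarray, eps: float) -> set[frozenset]:
    """Brute-force connected components of the <=eps graph, dropping singletons."""
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(xy[i] - xy[j])) <= eps:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values() if len(g) >= 2}


class TestDetect:
    def test_pair_within_eps(self, hr_frame):
        m = make_map(hr_frame, [(100, 100, "B"), (199, 100, "B")])
        neighs = detect_neighborhoods(m, NeighborhoodParams(eps_px=100))
        assert len(neighs) == 1 and neighs[0].size == 2

    def test_isolated_cell_is_noise(self, hr_frame):
        m = make_map(hr_frame, [(100, 100, "B")])
        assert detect_neighborhoods(m) == []

    def test_chain_links_transitively(self, hr_frame):
        m = make_map(hr_frame, [(100, 100, "B"), (180, 100, "B"), (260, 100, "B")])
        neighs = detect_neighborhoods(m, NeighborhoodParams(eps_px=100))
        assert len(neighs) == 1 and neighs[0].size == 3

    def test_matches_connected_component_oracle(self, hr_frame):
        """DBSCAN(min size 2) partition equals epsilon-graph components."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(2, 120))
            xy = rng.uniform(0, 1024, size=(n, 2))
            m = make_map(hr_frame, [(float(x), float(y), "B") for x, y in xy])
            got = {
                frozenset(neigh.member_ids)
                for neigh in detect_neighborhoods(m, NeighborhoodParams(eps_px=100))
            }
            assert got == eps_graph_components(xy, 100.0)

    def test_memberships_are_disjoint(self, hr_frame):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 1024, size=(150, 2))
        m = make_map(hr_frame, [(float(x), float(y), "B") for x, y in xy])
        neighs = detect_neighborhoods(m)
        seen: set[int] = set()
        for n_ in neighs:
            assert n_.size >= 2
            assert not (set(n_.member_ids) & seen)
            seen |= set(n_.member_ids)


class TestFeatures:
    def test_two_b_cells(self, hr_frame):
        m = make_map(hr_frame, [(100, 100, "B"), (150, 100, "B")])
        neigh = detect_neighborhoods(m)[0]
        f = dict(zip(FEATURE_NAMES, neighborhood_features(neigh, m)))
        assert f["count_1"] == 2 and f["prop_1"] == 1.0
        assert f["prop_2"] == f["prop_3"] == f["prop_4"] == f["prop_5"] == 0.0
        assert f["size"] == 2 and f["majority_prop"] == 1.0

    def test_pseudocount_ratio(self, hr_frame):
        m = make_map(
            hr_frame,
            [(100, 100, "B"), (110, 100, "B"), (120, 100, "B"), (100, 110, "CD4pos_T")],
        )
        neigh = detect_neighborhoods(m)[0]
        f = dict(zip(FEATURE_NAMES, neighborhood_features(neigh, m)))
        assert f["ratio_B_T"] == pytest.approx((3 + 1) / (1 + 1))

    def test_collinear_centroids_finite(self, hr_frame):
        m = make_map(hr_frame, [(100, 100, "B"), (150, 100, "B"), (200, 100, "B")])
        neigh = detect_neighborhoods(m)[0]
        f = neighborhood_features(neigh, m)
        assert np.all(np.isfinite(f))
        named = dict(zip(FEATURE_NAMES, f))
        # degenerate hull falls back to a 1-px strip along the 100 px diameter
        assert named["hull_area_um2"] == pytest.approx(100 * hr_frame.pixel_size_um**2)

    def test_translation_invariance(self, hr_frame):
        pts = [(100.0, 100.0, "B"), (130.0, 120.0, "CD4pos_T"), (160.0, 90.0, "B")]
        shifted = [(x + 300, y + 400, c) for x, y, c in pts]
        f1 = neighborhood_features(
            detect_neighborhoods(m1 := make_map(hr_frame, pts))[0], m1
        )
        f2 = neighborhood_features(
            detect_neighborhoods(m2 := make_map(hr_frame, shifted))[0], m2
        )
        assert np.allclose(f1, f2)

    def test_area_features_scale_with_pixel_size(self):
        pts = [(100.0, 100.0, "B"), (130.0, 120.0, "B"), (160.0, 90.0, "B")]
        f_hr = FrameMeta(1024, 1024, 0.1058, Mode.HR_ROI)
        f_big = FrameMeta(1024, 1024, 0.2116, Mode.HR_ROI)
        m1 = make_map(f_hr, pts)
        m2 = make_map(f_big, pts)
        a1 = dict(zip(FEATURE_NAMES, neighborhood_features(detect_neighborhoods(m1)[0], m1)))
        a2 = dict(zip(FEATURE_NAMES, neighborhood_features(detect_neighborhoods(m2)[0], m2)))
        assert a2["hull_area_um2"] == pytest.approx(4 * a1["hull_area_um2"])
        assert a2["max_pairwise_dist_um"] == pytest.approx(2 * a1["max_pairwise_dist_um"])


class TestKSelection:
    def test_planted_archetypes_recovered(self):
        X, labels, _ = sample_archetype_features(1200, seed=0)
        res = select_k_bootstrap_wcss(X, list(range(1, 10)), n_boot=5, seed=0)
        assert res.chosen_k == 6

    def test_single_gaussian_no_elbow(self):
        rng = np.random.default_rng(1)
        res = select_k_bootstrap_wcss(rng.normal(size=(600, 24)), list(range(1, 8)), n_boot=5, seed=1)
        assert res.chosen_k <= 2

    def test_same_seed_identical(self):
        X, _, _ = sample_archetype_features(400, seed=2)
        r1 = select_k_bootstrap_wcss(X, [1, 2, 3, 4], n_boot=3, seed=5)
        r2 = select_k_bootstrap_wcss(X, [1, 2, 3, 4], n_boot=3, seed=5)
        assert np.array_equal(r1.wcss, r2.wcss) and r1.chosen_k == r2.chosen_k

    def test_wcss_nonincreasing_in_k(self):
        X, _, _ = sample_archetype_features(600, seed=3)
        res = select_k_bootstrap_wcss(X, list(range(1, 8)), n_boot=5, seed=3)
        assert (np.diff(res.mean_wcss) <= 1e-6).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(InferenceError):
            select_k_bootstrap_wcss(np.zeros((3, 4)), [1, 2, 3, 4, 5])


class TestKMeans:
    def test_planted_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        X, labels, _ = sample_archetype_features(1200, seed=4)
        got, _ = kmeans_neighborhood_classes(X, 6, seed=0)
        assert adjusted_rand_score(labels, got) >= 0.95

    def test_k1_wcss_is_total_scatter(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 6))
        labels, centroids = kmeans_neighborhood_classes(X, 1, seed=0)
        assert set(labels) == {0}
        Z = (X - X.mean(0)) / X.std(0)
        # single-cluster WCSS equals the total scatter of the z-scored data
        assert np.allclose(centroids[0], Z.mean(0), atol=1e-8)

    def test_duplicating_rows_preserves_centroids(self):
        X, _, _ = sample_archetype_features(300, seed=6)
        _, c1 = kmeans_neighborhood_classes(X, 6, seed=0)
        _, c2 = kmeans_neighborhood_classes(np.vstack([X, X]), 6, seed=0)
        # compare as sets of centroids (label order may permute)
        d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=-1)
        assert d.min(axis=1).max() < 1e-6


class TestLooTests:
    def test_planted_shift_found(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 10))
        labels = np.zeros(300, dtype=int)
        labels[:100] = 1
        X[labels == 1, 3] += 3.0
        t = loo_feature_tests(X, labels)
        assert int(np.argmax(t.loc[1].to_numpy())) == 3

    def test_matches_direct_welch_t(self):
        X, labels, _ = sample_archetype_features(300, seed=8)
        t = loo_feature_tests(X, labels)
        lab = labels[0]
        direct, _ = stats.ttest_ind(X[labels == lab, 5], X[labels != lab, 5], equal_var=False)
        assert t.loc[lab].iloc[5] == pytest.approx(direct)

    def test_singleton_cluster_rejected(self):
        X = np.zeros((5, 3))
        labels = np.array([0, 0, 0, 0, 1])
        with pytest.raises(InferenceError):
            loo_feature_tests(X, labels)


class TestRules:
    def test_bt_rule_fires(self):
        assert classify_rule_based(20, {"B": 10, "CD4pos_T": 10}) == {"BT"}

    def test_all_b_19_cells_neither(self):
        assert classify_rule_based(19, {"B": 19}) == set()

    def test_cd4neg_quarter_fraction_inclusive(self):
        assert classify_rule_based(4, {"CD8_T": 1, "CD4_T": 3}, panel="HMP") == {"CD4neg"}

    def test_hr_panel_uses_cd4neg_class(self):
        assert classify_rule_based(4, {"CD4neg_T": 1, "CD4pos_T": 3}, panel="HR") == {"CD4neg"}

    def test_bt_requires_both_populations(self):
        assert classify_rule_based(30, {"B": 30}) == set()
        assert classify_rule_based(30, {"CD4pos_T": 30}) == set()


class TestPrevalence:
    def _cohort(self):
        c = CohortTable()
        for i in range(6):
            c.add(f"n{i}", Outcome.ESRD_neg, 4)
        for i in range(6):
            c.add(f"p{i}", Outcome.ESRD_pos, 4)
        return c

    def test_normalization(self):
        c = self._cohort()
        prev, _ = neighborhood_prevalence({"n0": 6}, c)
        assert prev["n0"] == pytest.approx(1.5)
        assert prev["n1"] == 0.0

    def test_planted_excess_detected(self):
        c = self._cohort()
        counts = {f"p{i}": 12 for i in range(6)}
        counts.update({f"n{i}": 2 for i in range(6)})
        _, tests = neighborhood_prevalence(counts, c, family=2)
        assert tests["p_corrected"].iloc[0] < 0.05

    def test_zero_rois_rejected(self):
        c = CohortTable()
        with pytest.raises(Exception):
            c.add("x", Outcome.ESRD_neg, 0)
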