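"""Per-ROI densities, Mann-Whitney/Bonferroni comparisons, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lnspatial.core import CellMap, CellRecord, Outcome
from lnspatial.density import (
    BootstrapParams,
    InferenceError,
    biopsy_totals,
    bonferroni,
    bootstrap_diff_distribution,
    bootstrap_mean_difference,
    bootstrap_summary,
    cohort_density_comparison,
    per_roi_densities,
    percentile_ci,
)

from conftest import make_map


def _roi(hr_frame, roi_id, biopsy_id, outcome, counts: dict[str, int]) -> CellMap:
    spec = []
    x = 10.0
    for cls, n in counts.items():
        for _ in range(n):
            spec.append((x, 10.0, cls))
            x += 1.0
    return make_map(spec=spec, frame=hr_frame, roi_id=roi_id, biopsy_id=biopsy_id, outcome=outcome)


class TestDensityTable:
    def test_counts_per_class(self, hr_frame):
        m = _roi(hr_frame, "r1", "b1", Outcome.ESRD_neg, {"B": 5, "CD4neg_T": 3})
        t = per_roi_densities([m])
        row = t.loc["r1"]
        assert row["B"] == 5 and row["CD4neg_T"] == 3
        assert row["CD4pos_T"] == 0 and row["total"] == 8

    def test_empty_roi_all_zero(self, hr_frame):
        m = CellMap(frame=hr_frame, cells=[], roi_id="r0")
        t = per_roi_densities([m])
        assert t.loc["r0", ["B", "CD4neg_T", "CD4pos_T", "pDC", "mDC", "total"]].sum() == 0

    def test_biopsy_totals_conserve_counts(self, hr_frame):
        maps = [
            _roi(hr_frame, "r1", "b1", Outcome.ESRD_neg, {"B": 2}),
            _roi(hr_frame, "r2", "b1", Outcome.ESRD_neg, {"B": 3, "mDC": 1}),
            _roi(hr_frame, "r3", "b2", Outcome.ESRD_pos, {"CD4neg_T": 4}),
        ]
        t = per_roi_densities(maps)
        tot = biopsy_totals(t)
        assert tot.loc["b1", "B"] == 5
        assert tot.loc["b1", "total"] == 6
        assert (tot.sum() == t.drop(columns=["biopsy_id", "outcome"]).sum()).all()


class TestMannWhitney:
    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.02, 5) == pytest.approx(0.10)
        assert bonferroni(0.5, 5) == 1.0

    def _table(self, rng, offset=0.0, n=200):
        rows = []
        for i in range(n):
            rows.append({"biopsy_id": "a", "outcome": "ESRD_neg", "B": rng.normal(10, 2)})
        for i in range(n):
            rows.append({"biopsy_id": "b", "outcome": "ESRD_pos", "B": rng.normal(10 + offset, 2)})
        return pd.DataFrame(rows)

    def test_null_rarely_significant(self):
        """Identical distributions: corrected p > 0.05 in >= 90% of 100 repeats."""
        rng = np.random.default_rng(0)
        hits = sum(
            cohort_density_comparison(self._table(rng), classes=["B"])["p_corrected"].iloc[0] > 0.05
            for _ in range(100)
        )
        assert hits >= 90

    def test_two_sd_offset_detected(self):
        """Groups 2 pooled SDs apart: corrected p < 0.05 in >= 95% of repeats."""
        rng = np.random.default_rng(1)
        reps = 60
        hits = sum(
            cohort_density_comparison(self._table(rng, offset=4.0), classes=["B"])["p_corrected"].iloc[0] < 0.05
            for _ in range(reps)
        )
        assert hits >= 0.95 * reps

    def test_small_group_rejected(self):
        df = pd.DataFrame(
            [
                {"biopsy_id": "a", "outcome": "ESRD_neg", "B": 1.0},
                {"biopsy_id": "b", "outcome": "ESRD_pos", "B": 2.0},
                {"biopsy_id": "b", "outcome": "ESRD_pos", "B": 3.0},
            ]
        )
        with pytest.raises(InferenceError):
            cohort_density_comparison(df, classes=["B"])


class TestBootstrap:
    def _table(self, rng, mu_pos=10.0, n=150):
        rows = [
            {"biopsy_id": "a", "outcome": "ESRD_neg", "B": rng.normal(10, 2)} for _ in range(n)
        ] + [
            {"biopsy_id": "b", "outcome": "ESRD_pos", "B": rng.normal(mu_pos, 2)} for _ in range(n)
        ]
        return pd.DataFrame(rows)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        t = self._table(rng)
        p = BootstrapParams(n_iterations=200, seed=11)
        r1 = bootstrap_mean_difference(t, params=p, classes=["B"])
        r2 = bootstrap_mean_difference(t, params=p, classes=["B"])
        assert np.array_equal(r1.per_class["B"][0].differences, r2.per_class["B"][0].differences)

    def test_distribution_centers_on_true_difference(self):
        """Mean of the bootstrap difference distribution ~ pool mean difference."""
        rng = np.random.default_rng(3)
        t = self._table(rng, mu_pos=6.0)
        r = bootstrap_mean_difference(t, params=BootstrapParams(seed=4), classes=["B"])
        pr = r.per_class["B"][0]
        pool_diff = (
            t.loc[t.outcome == "ESRD_neg", "B"].mean() - t.loc[t.outcome == "ESRD_pos", "B"].mean()
        )
        se = pr.differences.std()
        assert abs(pr.differences.mean() - pool_diff) < 3 * se / np.sqrt(len(pr.differences))

    def test_separated_pools_significant(self):
        """Mean difference 10 with SD 2: the 95% CI excludes 0."""
        rng = np.random.default_rng(5)
        t = self._table(rng, mu_pos=20.0)
        r = bootstrap_mean_difference(t, params=BootstrapParams(seed=6), classes=["B"])
        pr = r.per_class["B"][0]
        assert pr.significant and pr.ci_high < 0

    def test_three_group_evaluates_all_pairs(self, hr_frame):
        rng = np.random.default_rng(7)
        rows = []
        for g in ("ESRD_neg", "ESRD_pos", "ESRD_current"):
            for _ in range(30):
                rows.append({"biopsy_id": g, "outcome": g, "B": rng.normal(10, 2)})
        r = bootstrap_mean_difference(
            pd.DataFrame(rows), params=BootstrapParams(n_iterations=100, seed=8), groups=3, classes=["B"]
        )
        assert len(r.per_class["B"]) == 3

    def test_empty_pool_rejected(self):
        df = pd.DataFrame([{"biopsy_id": "a", "outcome": "ESRD_neg", "B": 1.0}])
        with pytest.raises(InferenceError):
            bootstrap_mean_difference(df, classes=["B"])

    def test_ci_bounds_ordered_and_summary_consistent(self):
        rng = np.random.default_rng(9)
        t = self._table(rng)
        r = bootstrap_mean_difference(t, params=BootstrapParams(n_iterations=300, seed=10), classes=["B"])
        s = bootstrap_summary(r)
        pr = r.per_class["B"][0]
        assert pr.ci_low <= pr.ci_high
        assert bool(s["significant"].iloc[0]) == pr.significant
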