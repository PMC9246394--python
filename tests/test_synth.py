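"""Synthetic generator: structures, cohorts, and perturbed detections."""

import numpy as np
import pytest
from scipy import ndimage

from lnspatial.core import FrameMeta, Mode, Outcome
from lnspatial.synth import (
    GLOMERULUS,
    TISSUE,
    TUBULE,
    PerturbSpec,
    SimConfig,
    StructureParams,
    generate_cohort,
    generate_structures,
    perturb_segmentation,
)


class TestStructures:
    def test_requested_glomeruli_are_disjoint_components(self):
        params = StructureParams(n_glomeruli=3, glomerulus_radius_px=(30, 40), tubule_area_fraction=0.2)
        labels = generate_structures(params, 512, 512, seed=0)
        _, n_comp = ndimage.label(labels == GLOMERULUS)
        assert n_comp == 3

    def test_same_seed_identical(self):
        params = StructureParams(n_glomeruli=2, glomerulus_radius_px=(30, 40))
        a = generate_structures(params, 512, 512, seed=7)
        b = generate_structures(params, 512, 512, seed=7)
        assert np.array_equal(a, b)

    def test_tubule_fraction_tracks_request(self):
        """Mean realized tubule fraction within 10% of the target over 20 seeds."""
        target = 0.25
        params = StructureParams(
            n_glomeruli=1, glomerulus_radius_px=(25, 35), tubule_area_fraction=target
        )
        fracs = []
        for seed in range(20):
            labels = generate_structures(params, 512, 512, seed=seed)
            fracs.append((labels == TUBULE).sum() / labels.size)
        assert abs(np.mean(fracs) - target) < 0.1 * target

    def test_labels_are_valid(self):
        params = StructureParams(n_glomeruli=1, glomerulus_radius_px=(25, 35))
        labels = generate_structures(params, 256, 256, seed=1)
        assert set(np.unique(labels)) <= {TISSUE, TUBULE, GLOMERULUS}


def _fast_hr_config(**kwargs) -> SimConfig:
    defaults = dict(
        n_esrd_neg=2,
        n_esrd_pos=2,
        n_esrd_current=1,
        rois_per_biopsy={"ESRD_neg": 3, "ESRD_pos": 3, "ESRD_current": 3},
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestCohort:
    def test_default_cohort_sizes(self):
        cfg = SimConfig(rois_per_biopsy={"ESRD_neg": 1, "ESRD_pos": 1, "ESRD_current": 1})
        _, cohort, _ = generate_cohort(cfg, seed=0)
        outcomes = [o for o, _, _ in cohort.entries.values()]
        assert len(cohort.entries) == 55
        assert outcomes.count(Outcome.ESRD_neg) == 36
        assert outcomes.count(Outcome.ESRD_pos) == 14
        assert outcomes.count(Outcome.ESRD_current) == 5

    def test_pure_poisson_counts_match_intensity(self):
        """With archetype rates 0, per-ROI counts are Poisson(lambda * area)."""
        lam = 2000.0
        cfg = SimConfig(
            n_esrd_neg=1,
            n_esrd_pos=0,
            n_esrd_current=0,
            rois_per_biopsy={"ESRD_neg": 200, "ESRD_pos": 1, "ESRD_current": 1},
            intensities={g: {"B": lam} for g in ("ESRD_neg", "ESRD_pos", "ESRD_current")},
            archetypes={},
        )
        maps, _, _ = generate_cohort(cfg, seed=1)
        # rois_per_biopsy is a Poisson mean; take however many were drawn
        counts = np.array([len(m) for m in maps])
        expected = lam * cfg.frame.area_mm2
        se = np.sqrt(expected / len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_same_seed_identical_tables(self):
        cfg = _fast_hr_config()
        a, _, _ = generate_cohort(cfg, seed=9)
        b, _, _ = generate_cohort(cfg, seed=9)
        assert len(a) == len(b)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.centroids(), mb.centroids())
            assert list(ma.classes()) == list(mb.classes())

    def test_all_centroids_in_frame(self):
        maps, _, _ = generate_cohort(_fast_hr_config(), seed=3)
        for m in maps:
            xy = m.centroids()
            if len(xy):
                assert xy[:, 0].min() >= 0 and xy[:, 0].max() <= m.frame.width_px
                assert xy[:, 1].min() >= 0 and xy[:, 1].max() <= m.frame.height_px

    def test_hmp_mode_emits_structures_and_markers(self):
        cfg = SimConfig(
            mode=Mode.HMP_SECTION,
            n_esrd_neg=1,
            n_esrd_pos=0,
            n_esrd_current=0,
            frame=FrameMeta(512, 512, 0.221, Mode.HMP_SECTION),
            structures=StructureParams(n_glomeruli=1, glomerulus_radius_px=(30, 40)),
        )
        maps, _, structs = generate_cohort(cfg, seed=2)
        assert len(maps) == 1 and len(structs) == 1
        flags = set().union(*(c.markers for c in maps[0].cells))
        assert flags & {"PD1", "FOXP3", "TCRdelta"}


class TestPerturb:
    @pytest.fixture
    def truth(self):
        cfg = _fast_hr_config(n_esrd_neg=1, n_esrd_pos=0, n_esrd_current=0, with_masks=True)
        maps, _, _ = generate_cohort(cfg, seed=4)
        return maps[0]

    def test_zero_spec_preserves_cells(self, truth):
        pred = perturb_segmentation(truth, PerturbSpec(), seed=0)
        assert len(pred) == len(truth)
        assert np.allclose(pred.centroids(), truth.centroids())
        assert list(pred.classes()) == list(truth.classes())
        for p in pred.cells:
            assert 0.7 <= p.confidence <= 1.0

    def test_drop_rate_gives_expected_recall(self):
        """Survivor fraction ~ Binomial(n, 1-d) within 3 SE over ~1000 cells."""
        cfg = SimConfig(
            n_esrd_neg=1,
            n_esrd_pos=0,
            n_esrd_current=0,
            rois_per_biopsy={"ESRD_neg": 12, "ESRD_pos": 1, "ESRD_current": 1},
            with_masks=False,
        )
        maps, _, _ = generate_cohort(cfg, seed=5)
        n = sum(len(m) for m in maps)
        kept = sum(
            len(perturb_segmentation(m, PerturbSpec(drop_rate=0.2), seed=i))
            for i, m in enumerate(maps)
        )
        d = 0.2
        se = np.sqrt(d * (1 - d) / n)
        assert abs(kept / n - (1 - d)) < 3 * se

    def test_spurious_cells_have_masks_and_confidences(self, truth):
        pred = perturb_segmentation(truth, PerturbSpec(spurious_rate=0.5), seed=1)
        assert len(pred) > len(truth)
        for c in pred.cells:
            assert c.mask is not None

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            PerturbSpec(drop_rate=1.5)
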