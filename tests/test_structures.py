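"""Tissue masks, compartment areas, and structure distances."""

import numpy as np
import pytest

from lnspatial.core import FrameMeta, Mode
from lnspatial.structures import (
    TissueMaskParams,
    cell_structure_distances,
    compartment_areas,
    compose_structure_mask,
    neighborhood_structure_distances,
    tissue_mask_from_dapi,
)
from lnspatial.synth import GLOMERULUS, TISSUE, TUBULE
from lnspatial.neighborhoods import Neighborhood

from conftest import make_map


class TestTissueMask:
    def test_constant_image_empty(self):
        assert not tissue_mask_from_dapi(np.zeros((64, 64))).any()

    def test_bright_disc_recovered(self):
        yy, xx = np.mgrid[0:256, 0:256]
        img = ((yy - 128) ** 2 + (xx - 128) ** 2 <= 60**2) * 200.0
        img += np.random.default_rng(0).uniform(0, 5, img.shape)
        mask = tissue_mask_from_dapi(img, TissueMaskParams(gaussian_sigma_px=2))
        disc_area = np.pi * 60**2
        assert abs(mask.sum() - disc_area) < 0.1 * disc_area

    def test_intensity_scaling_invariant(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (128, 128))
        img[30:90, 30:90] += 3.0
        m1 = tissue_mask_from_dapi(img, TissueMaskParams(gaussian_sigma_px=3))
        m2 = tissue_mask_from_dapi(img * 2.0, TissueMaskParams(gaussian_sigma_px=3))
        assert np.array_equal(m1, m2)


class TestCompose:
    def test_precedence_and_conservation(self):
        tissue = np.ones((32, 32), dtype=bool)
        tub = np.zeros_like(tissue)
        tub[0:10, 0:10] = True
        glom = np.zeros_like(tissue)
        glom[5:15, 5:15] = True
        smask = compose_structure_mask(tissue, tub, glom)
        assert (smask[5:10, 5:10] == GLOMERULUS).all()  # overlap goes to glomerulus
        areas = compartment_areas(smask)
        assert sum(areas.values()) == pytest.approx(1.0)

    def test_no_structures_all_ti(self):
        tissue = np.ones((16, 16), dtype=bool)
        smask = compose_structure_mask(tissue, np.zeros_like(tissue), np.zeros_like(tissue))
        assert compartment_areas(smask)["TI"] == 1.0

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose_structure_mask(np.ones((4, 4)), np.ones((5, 5)), np.ones((4, 4)))

    def test_analytic_disc_fraction(self):
        tissue = np.ones((512, 512), dtype=bool)
        yy, xx = np.mgrid[0:512, 0:512]
        glom = (yy - 256) ** 2 + (xx - 256) ** 2 <= 50**2
        smask = compose_structure_mask(tissue, np.zeros_like(tissue), glom)
        frac = compartment_areas(smask)["glomerulus"]
        assert frac == pytest.approx(np.pi * 50**2 / 512**2, rel=0.01)

    def test_fraction_invariant_under_rotation(self):
        tissue = np.ones((64, 64), dtype=bool)
        tub = np.zeros_like(tissue)
        tub[10:30, 5:20] = True
        smask = compose_structure_mask(tissue, tub, np.zeros_like(tissue))
        assert compartment_areas(np.rot90(smask)) == compartment_areas(smask)

    def test_empty_tissue_rejected(self):
        with pytest.raises(ValueError):
            compartment_areas(np.zeros((8, 8), dtype=np.uint8))


def _frame(w=256, h=256):
    return FrameMeta(w, h, 0.221, Mode.HMP_SECTION)


class TestCellDistances:
    def _smask(self):
        smask = np.full((256, 256), TISSUE, dtype=np.uint8)
        smask[100:120, 100:120] = TUBULE
        return smask

    def test_inside_target_zero(self):
        m = make_map(_frame(), [(105.3, 110.7, "B")])
        d = cell_structure_distances(m, self._smask(), TUBULE)
        assert d["distance_um"].iloc[0] == 0.0

    def test_ten_px_gap(self):
        # centroid at pixel center (90.5, 110.5); nearest tubule pixel center (100.5, 110.5)
        m = make_map(_frame(), [(90.5, 110.5, "B")])
        d = cell_structure_distances(m, self._smask(), TUBULE)
        assert d["distance_px"].iloc[0] == pytest.approx(10.0)
        assert d["distance_um"].iloc[0] == pytest.approx(2.21)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        smask = np.full((256, 256), TISSUE, dtype=np.uint8)
        pts = rng.integers(0, 256, size=(40, 2))
        smask[pts[:, 1], pts[:, 0]] = GLOMERULUS
        xy = rng.uniform(0, 256, size=(60, 2))
        m = make_map(_frame(), [(float(x), float(y), "B") for x, y in xy])
        d = cell_structure_distances(m, smask, GLOMERULUS)["distance_px"].to_numpy()
        ty, tx = np.nonzero(smask == GLOMERULUS)
        centers = np.column_stack([tx + 0.5, ty + 0.5])
        brute = np.array(
            [
                0.0
                if smask[int(np.floor(y)), int(np.floor(x))] == GLOMERULUS
                else np.min(np.hypot(centers[:, 0] - x, centers[:, 1] - y))
                for x, y in xy
            ]
        )
        assert np.allclose(d, brute)

    def test_lipschitz_in_centroid(self):
        smask = self._smask()
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.uniform(10, 240, 2)
            dx, dy = rng.uniform(-3, 3, 2)
            m1 = make_map(_frame(), [(x, y, "B")])
            m2 = make_map(_frame(), [(x + dx, y + dy, "B")])
            d1 = cell_structure_distances(m1, smask, TUBULE)["distance_px"].iloc[0]
            d2 = cell_structure_distances(m2, smask, TUBULE)["distance_px"].iloc[0]
            assert abs(d1 - d2) <= np.hypot(dx, dy) + 1e-9

    def test_absent_target_named(self):
        m = make_map(_frame(), [(5, 5, "B")])
        smask = np.full((256, 256), TISSUE, dtype=np.uint8)
        with pytest.raises(ValueError, match="glomerulus"):
            cell_structure_distances(m, smask, GLOMERULUS)


class TestNeighborhoodDistances:
    def test_mean_of_members_and_permutation_invariance(self):
        m = make_map(_frame(), [(10, 10, "B"), (20, 10, "B"), (30, 10, "B")])
        smask = np.full((256, 256), TISSUE, dtype=np.uint8)
        smask[:, 0] = TUBULE
        cd = cell_structure_distances(m, smask, TUBULE)
        n1 = Neighborhood(0, "roi0", [0, 1, 2])
        n2 = Neighborhood(1, "roi0", [2, 0, 1])
        out = neighborhood_structure_distances([n1, n2], cd)
        assert out["distance_um"].iloc[0] == pytest.approx(out["distance_um"].iloc[1])
        expected = cd["distance_um"].mean()
        assert out["distance_um"].iloc[0] == pytest.approx(expected)
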