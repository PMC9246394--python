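"""Synthetic biopsy generator: structures, cells, cohorts, perturbed detections.

The generator emulates the statistical structure the downstream analyses
assume, at two scales:

* **HR mode** — discrete 1024x1024 px regions of interest at 0.1058 um/px
  with five immune-cell classes (B, CD4- T, CD4+ T, pDC, mDC), many ROIs
  per biopsy;
* **HMP mode** — whole-section canvases at 0.221 um/px with five lymphocyte
  classes (CD4+ T, CD8+ T, DN T, B, plasma) plus PD1/ICOS/FoxP3 (and
  TCRdelta) marker flags, one section per biopsy, with tubule/glomerulus
  structure masks.

Cells arise from a superposition of a homogeneous Poisson background (per
class) and a Thomas-type parent-offspring cluster process per neighborhood
archetype: parents are a Poisson process with a per-archetype,
per-outcome-group intensity; each parent spawns a negative-binomial number
of offspring displaced by isotropic Gaussians.  Large B-T archetype parents
can be biased toward glomerular boundaries (periglomerular aggregates).
Outcome-group differences (B density, CD4- T density, CD4- neighborhood
rate, mDC depletion in current renal failure) are planted through the
group-specific intensities.

``perturb_segmentation`` produces a degraded "predicted" cell map from a
ground-truth map (drops, spurious detections, centroid jitter, mask
resizing, class flips, confidence sampling) for exercising the
detection-evaluation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from lnspatial.core import (
    CellMap,
    CellRecord,
    CohortTable,
    FrameMeta,
    Mode,
    Outcome,
    PANELS,
)

ARCHETYPES = (
    "B_enriched",
    "CD4neg_enriched",
    "BT_large",
    "CD4pos_enriched",
    "mDC_enriched",
    "pDC_enriched",
)

#: Structure-mask labels.
BACKGROUND, TISSUE, TUBULE, GLOMERULUS = 0, 1, 2, 3


class PlacementError(RuntimeError):
    """Requested structures could not be placed without overlap."""


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class StructureParams:
    """Geometry of synthetic tubule/glomerulus layouts (pixel units)."""

    n_glomeruli: int = 3
    glomerulus_radius_px: tuple[int, int] = (60, 90)
    tubule_area_fraction: float = 0.30
    tubule_axes_px: tuple[tuple[int, int], tuple[int, int]] = ((25, 60), (12, 30))
    margin_px: int = 4
    max_retries: int = 2000


@dataclass
class ClusterSpec:
    """One neighborhood archetype of the Thomas cluster process."""

    mixture: dict[str, float]
    mean_size: float
    dispersion: float = 4.0
    rates: dict[str, float] = field(default_factory=dict)  # outcome -> parents/mm^2
    periglomerular: bool = False


def _hr_intensities() -> dict[str, dict[str, float]]:
    # cells/mm^2 per outcome group; planted directions: B highest in ESRD-,
    # CD4- T highest in ESRD current, mDC depleted in ESRD current.
    return {
        "ESRD_neg": {"B": 2000, "CD4neg_T": 1200, "CD4pos_T": 1700, "pDC": 400, "mDC": 600},
        "ESRD_pos": {"B": 1000, "CD4neg_T": 2400, "CD4pos_T": 1700, "pDC": 400, "mDC": 600},
        "ESRD_current": {"B": 700, "CD4neg_T": 3600, "CD4pos_T": 1700, "pDC": 400, "mDC": 150},
    }


def _hmp_intensities() -> dict[str, dict[str, float]]:
    # Class balance follows the observed lymphocyte composition: CD4 T most
    # abundant, plasma second, B least; same planted outcome directions.
    return {
        "ESRD_neg": {"CD4_T": 700, "CD8_T": 250, "DN_T": 180, "B": 240, "plasma": 560},
        "ESRD_pos": {"CD4_T": 700, "CD8_T": 420, "DN_T": 300, "B": 120, "plasma": 560},
        "ESRD_current": {"CD4_T": 700, "CD8_T": 520, "DN_T": 380, "B": 90, "plasma": 560},
    }


def _hr_archetypes() -> dict[str, ClusterSpec]:
    return {
        "B_enriched": ClusterSpec(
            {"B": 0.80, "CD4pos_T": 0.10, "CD4neg_T": 0.05, "pDC": 0.025, "mDC": 0.025},
            mean_size=8,
            rates={"ESRD_neg": 30, "ESRD_pos": 15, "ESRD_current": 10},
        ),
        "CD4neg_enriched": ClusterSpec(
            {"CD4neg_T": 0.80, "CD4pos_T": 0.10, "B": 0.05, "pDC": 0.025, "mDC": 0.025},
            mean_size=5,
            dispersion=3.0,
            rates={"ESRD_neg": 15, "ESRD_pos": 30, "ESRD_current": 45},
        ),
        "BT_large": ClusterSpec(
            {"B": 0.30, "CD4pos_T": 0.48, "CD4neg_T": 0.12, "pDC": 0.05, "mDC": 0.05},
            mean_size=35,
            dispersion=10.0,
            rates={"ESRD_neg": 8, "ESRD_pos": 8, "ESRD_current": 8},
            periglomerular=True,
        ),
        "CD4pos_enriched": ClusterSpec(
            {"CD4pos_T": 0.80, "CD4neg_T": 0.08, "B": 0.06, "pDC": 0.03, "mDC": 0.03},
            mean_size=8,
            rates={"ESRD_neg": 20, "ESRD_pos": 20, "ESRD_current": 20},
        ),
        "mDC_enriched": ClusterSpec(
            {"mDC": 0.80, "pDC": 0.05, "CD4pos_T": 0.08, "CD4neg_T": 0.05, "B": 0.02},
            mean_size=6,
            rates={"ESRD_neg": 8, "ESRD_pos": 8, "ESRD_current": 2},
        ),
        "pDC_enriched": ClusterSpec(
            {"pDC": 0.80, "mDC": 0.05, "CD4pos_T": 0.08, "CD4neg_T": 0.05, "B": 0.02},
            mean_size=6,
            rates={"ESRD_neg": 8, "ESRD_pos": 8, "ESRD_current": 8},
        ),
    }


def _hmp_archetypes() -> dict[str, ClusterSpec]:
    # DC archetypes have no counterpart in the HMP panel; the analogous
    # compact aggregates are plasma- and DN-enriched.
    return {
        "B_enriched": ClusterSpec(
            {"B": 0.70, "plasma": 0.15, "CD4_T": 0.10, "CD8_T": 0.03, "DN_T": 0.02},
            mean_size=8,
            rates={"ESRD_neg": 30, "ESRD_pos": 15, "ESRD_current": 10},
        ),
        "CD4neg_enriched": ClusterSpec(
            {"CD8_T": 0.45, "DN_T": 0.35, "CD4_T": 0.10, "B": 0.05, "plasma": 0.05},
            mean_size=5,
            dispersion=3.0,
            rates={"ESRD_neg": 15, "ESRD_pos": 30, "ESRD_current": 45},
        ),
        "BT_large": ClusterSpec(
            {"B": 0.25, "CD4_T": 0.45, "CD8_T": 0.08, "DN_T": 0.05, "plasma": 0.17},
            mean_size=35,
            dispersion=10.0,
            rates={"ESRD_neg": 8, "ESRD_pos": 8, "ESRD_current": 8},
            periglomerular=True,
        ),
        "CD4pos_enriched": ClusterSpec(
            {"CD4_T": 0.80, "CD8_T": 0.08, "DN_T": 0.04, "B": 0.04, "plasma": 0.04},
            mean_size=8,
            rates={"ESRD_neg": 20, "ESRD_pos": 20, "ESRD_current": 20},
        ),
        "mDC_enriched": ClusterSpec(
            {"plasma": 0.80, "CD4_T": 0.10, "B": 0.05, "CD8_T": 0.03, "DN_T": 0.02},
            mean_size=6,
            rates={"ESRD_neg": 8, "ESRD_pos": 8, "ESRD_current": 2},
        ),
        "pDC_enriched": ClusterSpec(
            {"DN_T": 0.60, "CD8_T": 0.20, "CD4_T": 0.10, "B": 0.05, "plasma": 0.05},
            mean_size=6,
            rates={"ESRD_neg": 8, "ESRD_pos": 8, "ESRD_current": 8},
        ),
    }


@dataclass
class MarkerProbs:
    """Conditional marker-flag probabilities for the HMP panel."""

    p_tfh_cd4_bt: float = 0.36        # P(Tfh | CD4 T in a B-T cluster)
    p_tfh_cd4_bg: float = 0.28        # P(Tfh | CD4 T elsewhere)
    p_icos_given_tfh: float = 0.17    # strict (PD1+ICOS+) share of the compartment
    p_treg_cd4: float = 0.025         # FoxP3+PD1-ICOS-
    p_exhausted_cd8: float = 0.25     # PD1+ICOS-FoxP3-
    p_foxp3_cd8: float = 0.013
    p_foxp3_dn: float = 0.0088
    p_tcrdelta_dn: float = 0.514


@dataclass
class SimConfig:
    """Full configuration of a synthetic cohort.

    Defaults emulate the study cohorts: 36 ESRD-, 14 ESRD+, and 5
    ESRD-current biopsies; mean ROI counts per biopsy of 12 / 19 / 32 in
    HR mode (one whole section per biopsy in HMP mode); cluster offspring
    displaced by sigma = 5 um so within-cluster nearest-neighbor gaps fall
    under the ~10.6 um neighborhood radius.
    """

    mode: Mode = Mode.HR_ROI
    n_esrd_neg: int = 36
    n_esrd_pos: int = 14
    n_esrd_current: int = 5
    rois_per_biopsy: dict[str, float] = field(
        default_factory=lambda: {"ESRD_neg": 12, "ESRD_pos": 19, "ESRD_current": 32}
    )
    frame: FrameMeta | None = None
    intensities: dict[str, dict[str, float]] | None = None
    archetypes: dict[str, ClusterSpec] | None = None
    cluster_sigma_um: float = 5.0
    periglomerular_max_dist_px: float = 40.0
    marker_probs: MarkerProbs = field(default_factory=MarkerProbs)
    structures: StructureParams | None = None
    with_masks: bool = False
    cell_radius_px: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        if self.frame is None:
            self.frame = (
                FrameMeta(1024, 1024, 0.1058, Mode.HR_ROI)
                if self.mode is Mode.HR_ROI
                else FrameMeta(2048, 2048, 0.221, Mode.HMP_SECTION)
            )
        if self.intensities is None:
            self.intensities = _hr_intensities() if self.mode is Mode.HR_ROI else _hmp_intensities()
        if self.archetypes is None:
            self.archetypes = _hr_archetypes() if self.mode is Mode.HR_ROI else _hmp_archetypes()
        if self.structures is None and self.mode is Mode.HMP_SECTION:
            self.structures = StructureParams()
        if self.cell_radius_px is None:
            # lymphocyte-scale discs (~5-8 um diameter) at the mode's pixel size
            self.cell_radius_px = (25, 40) if self.mode is Mode.HR_ROI else (12, 19)
        for group, per_class in self.intensities.items():
            for cls, lam in per_class.items():
                if lam < 0:
                    raise ConfigError(f"negative intensity for {group}/{cls}")
        for name, spec in self.archetypes.items():
            if spec.mean_size < 0 or spec.dispersion <= 0:
                raise ConfigError(f"bad cluster size parameters for {name}")
            if any(r < 0 for r in spec.rates.values()):
                raise ConfigError(f"negative archetype rate for {name}")
        if min(self.n_esrd_neg, self.n_esrd_pos, self.n_esrd_current) < 0:
            raise ConfigError("cohort sizes must be nonnegative")

    @property
    def panel(self) -> tuple[str, ...]:
        return PANELS["HR"] if self.mode is Mode.HR_ROI else PANELS["HMP"]


@dataclass
class PerturbSpec:
    """Degradation applied to a ground-truth map to mimic a detector.

    ``drop_rate`` removes true cells; ``spurious_rate`` adds false cells
    (expected count = rate x n_true); ``jitter_px`` shifts centroids and
    masks; ``resize_range`` erodes/dilates disc masks by a radius offset;
    ``class_flip_rate`` relabels kept cells.
    """

    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    jitter_px: float = 0.0
    resize_range: tuple[int, int] = (0, 0)
    class_flip_rate: float = 0.0
    conf_true: tuple[float, float] = (0.7, 1.0)
    conf_spurious: tuple[float, float] = (0.35, 0.95)

    def __post_init__(self) -> None:
        if not 0 <= self.drop_rate <= 1 or not 0 <= self.class_flip_rate <= 1:
            raise ConfigError("rates must lie in [0, 1]")
        if self.spurious_rate < 0 or self.jitter_px < 0:
            raise ConfigError("spurious_rate and jitter_px must be nonnegative")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


def generate_structures(
    params: StructureParams, width_px: int, height_px: int, seed: int
) -> np.ndarray:
    """Place non-overlapping glomerulus discs and tubule ellipses in tissue.

    Returns a ``(height, width)`` uint8 label image with labels background=0
    (unused here: tissue fills the canvas), TI tissue=1, tubule=2,
    glomerulus=3.  Glomeruli take precedence over tubules.  Raises
    :class:`PlacementError` when the requested layout cannot be placed
    within the retry budget.
    """
    if width_px <= 0 or height_px <= 0:
        raise ConfigError("canvas dims must be positive")
    rng = np.random.default_rng(seed)
    labels = np.full((height_px, width_px), TISSUE, dtype=np.uint8)
    occupied = np.zeros_like(labels, dtype=bool)
    m = params.margin_px

    def try_place(rr, cc) -> bool:
        if rr.size == 0:
            return False
        if occupied[rr, cc].any():
            return False
        return True

    placed = 0
    for _ in range(params.max_retries):
        if placed == params.n_glomeruli:
            break
        r = rng.integers(params.glomerulus_radius_px[0], params.glomerulus_radius_px[1] + 1)
        cy = rng.uniform(r + m, height_px - r - m)
        cx = rng.uniform(r + m, width_px - r - m)
        rr, cc = draw_disk((cy, cx), r + m, shape=labels.shape)
        if try_place(rr, cc):
            occupied[rr, cc] = True
            rr2, cc2 = draw_disk((cy, cx), r, shape=labels.shape)
            labels[rr2, cc2] = GLOMERULUS
            placed += 1
    if placed < params.n_glomeruli:
        raise PlacementError(
            f"placed only {placed}/{params.n_glomeruli} glomeruli in {params.max_retries} tries"
        )

    target = params.tubule_area_fraction * labels.size
    tubule_px = 0
    (a_lo, a_hi), (b_lo, b_hi) = params.tubule_axes_px
    for _ in range(params.max_retries):
        if tubule_px >= target:
            break
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(b_lo, b_hi)
        approx = np.pi * a * b
        remaining = target - tubule_px
        if approx > remaining:
            scale = max(np.sqrt(remaining / approx), b_lo / b)
            a, b = a * scale, b * scale
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(a + m, height_px - a - m)
        cx = rng.uniform(a + m, width_px - a - m)
        rr, cc = draw_ellipse(cy, cx, a + m, b + m, shape=labels.shape, rotation=theta)
        if try_place(rr, cc):
            occupied[rr, cc] = True
            rr2, cc2 = draw_ellipse(cy, cx, a, b, shape=labels.shape, rotation=theta)
            labels[rr2, cc2] = TUBULE
            tubule_px += len(rr2)
    if tubule_px < 0.8 * target:
        raise PlacementError(
            f"tubule area {tubule_px/labels.size:.3f} below 80% of requested "
            f"{params.tubule_area_fraction:.3f} after {params.max_retries} tries"
        )
    return labels


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------


def _disc_mask(x: float, y: float, radius: int, frame: FrameMeta) -> np.ndarray:
    rr, cc = draw_disk((y, x), radius, shape=(frame.height_px, frame.width_px))
    return np.column_stack([cc, rr]).astype(np.int64)


def _assign_markers(rng, base_class: str, in_bt: bool, mp: MarkerProbs) -> frozenset[str]:
    flags: set[str] = set()
    if base_class == "CD4_T":
        u = rng.uniform()
        if u < mp.p_treg_cd4:
            flags.add("FOXP3")
        else:
            p_tfh = mp.p_tfh_cd4_bt if in_bt else mp.p_tfh_cd4_bg
            if rng.uniform() < p_tfh:
                flags.add("PD1")
                if rng.uniform() < mp.p_icos_given_tfh / max(p_tfh, 1e-12):
                    flags.add("ICOS")
    elif base_class == "CD8_T":
        if rng.uniform() < mp.p_exhausted_cd8:
            flags.add("PD1")
        elif rng.uniform() < mp.p_foxp3_cd8:
            flags.add("FOXP3")
    elif base_class == "DN_T":
        if rng.uniform() < mp.p_foxp3_dn:
            flags.add("FOXP3")
        if rng.uniform() < mp.p_tcrdelta_dn:
            flags.add("TCRdelta")
    return frozenset(flags)


def _sample_frame_cells(
    rng: np.random.Generator,
    config: SimConfig,
    group: str,
    roi_id: str,
    biopsy_id: str,
    outcome: Outcome,
    smask: np.ndarray | None,
) -> CellMap:
    """Sample one ROI (HR) or section (HMP): Poisson background + clusters."""
    frame = config.frame
    area = frame.area_mm2
    sigma_px = config.cluster_sigma_um / frame.pixel_size_um
    xs: list[float] = []
    ys: list[float] = []
    classes: list[str] = []
    in_bt: list[bool] = []
    panel = list(config.panel)

    for cls, lam in config.intensities[group].items():
        n = rng.poisson(lam * area)
        if n == 0:
            continue
        xs.extend(rng.uniform(0, frame.width_px, n))
        ys.extend(rng.uniform(0, frame.height_px, n))
        classes.extend([cls] * n)
        in_bt.extend([False] * n)

    glom_boundary = None
    if smask is not None and (smask == GLOMERULUS).any():
        from scipy import ndimage

        glom = smask == GLOMERULUS
        boundary = glom ^ ndimage.binary_erosion(glom)
        by, bx = np.nonzero(boundary)
        glom_boundary = np.column_stack([bx, by]).astype(float)

    for name, spec in config.archetypes.items():
        rate = spec.rates.get(group, 0.0)
        n_parents = rng.poisson(rate * area)
        for _ in range(n_parents):
            if spec.periglomerular and glom_boundary is not None:
                anchor = glom_boundary[rng.integers(len(glom_boundary))]
                ang = rng.uniform(0, 2 * np.pi)
                d = rng.uniform(0, config.periglomerular_max_dist_px)
                px_ = np.clip(anchor[0] + d * np.cos(ang), 1, frame.width_px - 1)
                py_ = np.clip(anchor[1] + d * np.sin(ang), 1, frame.height_px - 1)
            else:
                px_ = rng.uniform(0, frame.width_px)
                py_ = rng.uniform(0, frame.height_px)
            k = spec.dispersion
            mean = spec.mean_size
            n_off = rng.negative_binomial(k, k / (k + mean))
            n_off = max(int(n_off), 2)
            ox = np.clip(px_ + rng.normal(0, sigma_px, n_off), 0, frame.width_px - 1e-6)
            oy = np.clip(py_ + rng.normal(0, sigma_px, n_off), 0, frame.height_px - 1e-6)
            probs = np.array([spec.mixture.get(c, 0.0) for c in panel])
            probs = probs / probs.sum()
            ocls = rng.choice(panel, size=n_off, p=probs)
            xs.extend(ox)
            ys.extend(oy)
            classes.extend(ocls)
            in_bt.extend([name == "BT_large"] * n_off)

    cells = []
    r_lo, r_hi = config.cell_radius_px
    for i in range(len(xs)):
        markers = (
            _assign_markers(rng, classes[i], in_bt[i], config.marker_probs)
            if config.mode is Mode.HMP_SECTION
            else frozenset()
        )
        mask = None
        if config.with_masks:
            mask = _disc_mask(xs[i], ys[i], int(rng.integers(r_lo, r_hi + 1)), frame)
        cells.append(
            CellRecord(
                cell_id=i,
                x=float(xs[i]),
                y=float(ys[i]),
                base_class=str(classes[i]),
                markers=markers,
                mask=mask,
            )
        )
    return CellMap(
        frame=frame,
        cells=cells,
        roi_id=roi_id,
        biopsy_id=biopsy_id,
        outcome=outcome,
    )


def generate_cohort(
    config: SimConfig, seed: int
) -> tuple[list[CellMap], CohortTable, dict[str, np.ndarray]]:
    """Generate a full synthetic cohort.

    Returns ``(cellmaps, cohort_table, structures)`` where ``structures``
    maps ``roi_id`` to its structure-mask label image (HMP mode only; empty
    in HR mode).  Same seed, same output.
    """
    rng = np.random.default_rng(seed)
    groups = (
        [("ESRD_neg", Outcome.ESRD_neg)] * config.n_esrd_neg
        + [("ESRD_pos", Outcome.ESRD_pos)] * config.n_esrd_pos
        + [("ESRD_current", Outcome.ESRD_current)] * config.n_esrd_current
    )
    cellmaps: list[CellMap] = []
    cohort = CohortTable()
    structures: dict[str, np.ndarray] = {}

    for b_idx, (group, outcome) in enumerate(groups):
        biopsy_id = f"biopsy{b_idx:03d}"
        if config.mode is Mode.HR_ROI:
            mean_rois = config.rois_per_biopsy[group]
            n_rois = max(1, int(rng.poisson(mean_rois)))
            for r in range(n_rois):
                roi_id = f"{biopsy_id}_roi{r:03d}"
                cellmaps.append(
                    _sample_frame_cells(
                        rng, config, group, roi_id, biopsy_id, outcome, None
                    )
                )
            cohort.add(biopsy_id, outcome, n_rois, chronicity=int(rng.integers(0, 7)))
        else:
            roi_id = f"{biopsy_id}_section"
            smask = None
            if config.structures is not None:
                smask = generate_structures(
                    config.structures,
                    config.frame.width_px,
                    config.frame.height_px,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                structures[roi_id] = smask
            cellmaps.append(
                _sample_frame_cells(rng, config, group, roi_id, biopsy_id, outcome, smask)
            )
            cohort.add(biopsy_id, outcome, 1, chronicity=int(rng.integers(0, 7)))
    return cellmaps, cohort, structures


# ---------------------------------------------------------------------------
# Segmentation perturbation
# ---------------------------------------------------------------------------


def _resize_disc(mask: np.ndarray, delta: int, cx: float, cy: float, frame: FrameMeta) -> np.ndarray:
    """Erode (delta<0) or dilate (delta>0) an approximately-disc mask."""
    if delta == 0 or mask is None:
        return mask
    r_eff = max(1, int(round(np.sqrt(len(mask) / np.pi))) + delta)
    return _disc_mask(cx, cy, r_eff, frame)


def perturb_segmentation(truth: CellMap, spec: PerturbSpec, seed: int) -> CellMap:
    """Degrade a ground-truth map into a synthetic detector output.

    Each true cell survives with probability ``1 - drop_rate``; survivors
    are jittered, optionally resized, and class-flipped with probability
    ``class_flip_rate``.  ``Poisson(spurious_rate * n_true)`` spurious cells
    are added uniformly with masks sampled from the true size distribution.
    Confidences are drawn from the true/spurious uniform ranges.
    """
    rng = np.random.default_rng(seed)
    frame = truth.frame
    panel = list(frame.panel)
    preds: list[CellRecord] = []
    next_id = 0

    true_radii = [
        max(1, int(round(np.sqrt(c.area_px / np.pi)))) for c in truth.cells if c.mask is not None
    ]

    for c in truth.cells:
        if rng.uniform() < spec.drop_rate:
            continue
        dx = rng.normal(0, spec.jitter_px) if spec.jitter_px > 0 else 0.0
        dy = rng.normal(0, spec.jitter_px) if spec.jitter_px > 0 else 0.0
        nx = float(np.clip(c.x + dx, 0, frame.width_px - 1e-6))
        ny = float(np.clip(c.y + dy, 0, frame.height_px - 1e-6))
        mask = c.mask
        if mask is not None:
            sdx, sdy = int(round(nx - c.x)), int(round(ny - c.y))
            if sdx or sdy:
                shifted = mask + np.array([sdx, sdy])
                keep = (
                    (shifted[:, 0] >= 0)
                    & (shifted[:, 0] < frame.width_px)
                    & (shifted[:, 1] >= 0)
                    & (shifted[:, 1] < frame.height_px)
                )
                mask = shifted[keep]
            lo, hi = spec.resize_range
            delta = int(rng.integers(lo, hi + 1)) if (lo, hi) != (0, 0) else 0
            mask = _resize_disc(mask, delta, nx, ny, frame)
        cls = c.base_class
        if spec.class_flip_rate > 0 and rng.uniform() < spec.class_flip_rate:
            cls = str(rng.choice([p for p in panel if p != cls]))
        preds.append(
            CellRecord(
                cell_id=next_id,
                x=nx,
                y=ny,
                base_class=cls,
                markers=c.markers,
                mask=mask,
                area_px=c.area_px if mask is None else 0.0,
                confidence=float(rng.uniform(*spec.conf_true)),
            )
        )
        next_id += 1

    n_spurious = rng.poisson(spec.spurious_rate * len(truth.cells))
    for _ in range(n_spurious):
        sx = float(rng.uniform(0, frame.width_px))
        sy = float(rng.uniform(0, frame.height_px))
        mask = None
        if true_radii:
            mask = _disc_mask(sx, sy, int(rng.choice(true_radii)), frame)
        preds.append(
            CellRecord(
                cell_id=next_id,
                x=sx,
                y=sy,
                base_class=str(rng.choice(panel)),
                mask=mask,
                confidence=float(rng.uniform(*spec.conf_spurious)),
            )
        )
        next_id += 1

    return CellMap(
        frame=frame,
        cells=preds,
        roi_id=truth.roi_id,
        biopsy_id=truth.biopsy_id,
        outcome=truth.outcome,
        chronicity=truth.chronicity,
    )


# ---------------------------------------------------------------------------
# Planted feature archetypes (for k-selection / archetype-recovery checks)
# ---------------------------------------------------------------------------

#: Feature indices upshifted per planted archetype (into the 24-feature
#: vector of :mod:`lnspatial.neighborhoods`).  Each archetype elevates the
#: count and proportion of its enriched class plus correlated companions
#: (the large B-T archetype elevates size/area/extent); the signatures
#: partition the 24 features so every archetype is separable.
PLANTED_SIGNATURES: dict[str, tuple[int, ...]] = {
    "B_enriched": (0, 5, 13, 23),
    "CD4neg_enriched": (1, 6, 12, 22),
    "BT_large": (2, 10, 11, 21),
    "CD4pos_enriched": (7, 14, 16, 18),
    "mDC_enriched": (4, 9, 15, 17),
    "pDC_enriched": (3, 8, 19, 20),
}


def sample_archetype_features(
    n: int, seed: int, shift: float = 6.0, n_features: int = 24
) -> tuple[np.ndarray, np.ndarray, dict[str, tuple[int, ...]]]:
    """Draw a planted-archetype feature matrix.

    Rows are split evenly over the six archetypes; each archetype's
    signature features are shifted ``+shift`` standard deviations above the
    unit-Gaussian base.  Returns ``(X, labels, signatures)`` where labels
    index into :data:`ARCHETYPES`.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(n, n_features))
    labels = np.arange(n) % len(ARCHETYPES)
    rng.shuffle(labels)
    for a_idx, name in enumerate(ARCHETYPES):
        rows = labels == a_idx
        for f in PLANTED_SIGNATURES[name]:
            X[rows, f] += shift
    return X, labels, dict(PLANTED_SIGNATURES)
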