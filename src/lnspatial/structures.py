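"""Tissue/structure mask processing and structure-proximity analysis.

The structure mask is a per-pixel label image over one frame: background=0,
tubulointerstitial (TI) tissue=1, tubule=2, glomerulus=3, with precedence
glomerulus > tubule > TI.  Compartment areas are pixel-count fractions of
total tissue.  Cell-to-structure distance is the minimum Euclidean distance
from a cell centroid to the center of any pixel carrying the target label
(zero when the centroid lies inside the target), reported in microns.
Neighborhood-to-structure distance is the mean of the member-cell
distances, and rule-label groups (B-T vs CD4- vs other) are compared by
Mann-Whitney U with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage import filters

from lnspatial.core import CellMap
from lnspatial.neighborhoods import Neighborhood
from lnspatial.synth import BACKGROUND, GLOMERULUS, TISSUE, TUBULE

LABEL_NAMES = {BACKGROUND: "background", TISSUE: "TI", TUBULE: "tubule", GLOMERULUS: "glomerulus"}


@dataclass(frozen=True)
class TissueMaskParams:
    gamma: float = 0.5
    gaussian_sigma_px: float = 8.0
    min_component_px: int = 512
    max_hole_px: int = 4096

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.gaussian_sigma_px <= 0:
            raise ValueError("gamma and gaussian_sigma_px must be positive")


def tissue_mask_from_dapi(image: np.ndarray, params: TissueMaskParams | None = None) -> np.ndarray:
    """Binary tissue mask from a nuclear-stain channel.

    Gamma-correct to lift dim tissue, Gaussian-filter, min-max normalize,
    then Otsu-threshold; small components are removed and small holes
    filled.  A constant image yields an empty mask.  The normalization step
    makes the result invariant to global intensity scaling.
    """
    params = params or TissueMaskParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or (img < 0).any():
        raise ValueError("expected a single-channel nonnegative image")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    img = img / img.max()
    img = img**params.gamma
    img = ndimage.gaussian_filter(img, params.gaussian_sigma_px)
    img = (img - img.min()) / (img.max() - img.min())
    mask = img > filters.threshold_otsu(img)

    from skimage import morphology

    mask = morphology.remove_small_objects(mask, params.min_component_px)
    mask = morphology.remove_small_holes(mask, params.max_hole_px)
    return mask


def compose_structure_mask(
    tissue: np.ndarray, tubule_mask: np.ndarray, glomeruli_mask: np.ndarray
) -> np.ndarray:
    """Merge binary masks into one label image (glomerulus > tubule > TI)."""
    if not (tissue.shape == tubule_mask.shape == glomeruli_mask.shape):
        raise ValueError("masks must share a frame")
    labels = np.zeros(tissue.shape, dtype=np.uint8)
    labels[tissue.astype(bool)] = TISSUE
    labels[tubule_mask.astype(bool)] = TUBULE
    labels[glomeruli_mask.astype(bool)] = GLOMERULUS
    return labels


def compartment_areas(smask: np.ndarray) -> dict[str, float]:
    """Fractions of total tissue occupied by TI, tubules, and glomeruli."""
    tissue_px = int((smask != BACKGROUND).sum())
    if tissue_px == 0:
        raise ValueError("structure mask contains no tissue")
    return {
        "TI": int((smask == TISSUE).sum()) / tissue_px,
        "tubule": int((smask == TUBULE).sum()) / tissue_px,
        "glomerulus": int((smask == GLOMERULUS).sum()) / tissue_px,
    }


def cell_structure_distances(
    cellmap: CellMap, smask: np.ndarray, target_label: int
) -> pd.DataFrame:
    """Minimum centroid-to-target-pixel distance per cell, in microns.

    The distance is zero when the pixel containing the centroid carries the
    target label; otherwise it is the minimum Euclidean distance to any
    target pixel center.  Raises ``ValueError`` when the target label is
    absent from the mask.
    """
    target = smask == target_label
    if not target.any():
        raise ValueError(f"label {LABEL_NAMES.get(target_label, target_label)} absent from mask")
    ty, tx = np.nonzero(target)
    centers = np.column_stack([tx + 0.5, ty + 0.5])
    tree = cKDTree(centers)
    ps = cellmap.frame.pixel_size_um
    rows = []
    for c in cellmap.cells:
        px, py = int(np.floor(c.x)), int(np.floor(c.y))
        inside = (
            0 <= py < smask.shape[0] and 0 <= px < smask.shape[1] and target[py, px]
        )
        if inside:
            d_px = 0.0
        else:
            _, idx = tree.query([c.x, c.y])
            d_px = float(np.hypot(centers[idx, 0] - c.x, centers[idx, 1] - c.y))
        rows.append(
            {
                "cell_id": c.cell_id,
                "base_class": c.base_class,
                "distance_px": float(d_px),
                "distance_um": float(d_px) * ps,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "base_class", "distance_px", "distance_um"])


def neighborhood_structure_distances(
    neighs: list[Neighborhood], cell_distances: pd.DataFrame
) -> pd.DataFrame:
    """Mean member-cell distance per neighborhood, with its rule label.

    ``cell_distances`` is the output of :func:`cell_structure_distances`
    for the frame the neighborhoods came from.  The rule label reported is
    ``"BT"`` or ``"CD4neg"`` when assigned, ``"other"`` otherwise.
    """
    dist_by_id = dict(zip(cell_distances["cell_id"], cell_distances["distance_um"]))
    rows = []
    for n in neighs:
        ds = [dist_by_id[i] for i in n.member_ids if i in dist_by_id]
        if not ds:
            continue
        if "BT" in n.rule_labels:
            label = "BT"
        elif "CD4neg" in n.rule_labels:
            label = "CD4neg"
        else:
            label = "other"
        rows.append(
            {
                "roi_id": n.roi_id,
                "neigh_id": n.neigh_id,
                "rule_label": label,
                "size": n.size,
                "distance_um": float(np.mean(ds)),
            }
        )
    return pd.DataFrame(rows, columns=["roi_id", "neigh_id", "rule_label", "size", "distance_um"])


def compare_rule_groups(neigh_distances: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests of distance between rule-label groups."""
    groups = [g for g in ("BT", "CD4neg", "other") if (neigh_distances["rule_label"] == g).any()]
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    rows = []
    for a, b in pairs:
        va = neigh_distances.loc[neigh_distances["rule_label"] == a, "distance_um"]
        vb = neigh_distances.loc[neigh_distances["rule_label"] == b, "distance_um"]
        if len(va) < 2 or len(vb) < 2:
            continue
        _, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "median_a": float(va.median()),
                "median_b": float(vb.median()),
                "p_raw": p,
                "p_corrected": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "median_a", "median_b", "p_raw", "p_corrected"])


def write_structure_mask(smask: np.ndarray, path) -> None:
    tifffile.imwrite(path, smask.astype(np.uint16))


def read_structure_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.uint8)
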