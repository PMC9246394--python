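"""Cellular-neighborhood discovery, description, and classification.

Neighborhoods are found with DBSCAN over cell centroids using a maximum
centroid-to-centroid distance of roughly 10 um (epsilon = 100 px in the HR
dataset, 50 px in the HMP dataset) and a minimum cluster size of 2.  With
that minimum size the DBSCAN partition coincides with the connected
components of the graph joining cells at distance <= epsilon, with isolated
cells discarded as noise.

Each neighborhood is summarized by 24 quantitative features covering cell
constituency (class counts and proportions, pseudocount ratios), size and
extent (cell count, convex-hull area, density, pairwise and
nearest-neighbor distances), and cell/neighborhood shape (cell area and
eccentricity moments, hull aspect ratio and circularity, majority-class
share).  Archetypes are discovered by K-means over z-scored features with
the number of classes chosen by bootstrapping the within-cluster sum of
squares (WCSS) and its decrement across k, and are described by
leave-one-out Welch t tests of each archetype against the pooled rest.

Two rule classifiers mirror the field definitions: large B-T (TLS-like)
neighborhoods — at least 20 cells, both B and CD4+ T cells present, and at
least 50% of cells B and/or CD4+ T — and small CD4- T neighborhoods —
fewer than 20 cells with >= 25% CD4- T cells (CD8+ or DN in the HMP
panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import DBSCAN, KMeans

from lnspatial.core import CellMap, CohortTable, Outcome
from lnspatial.density import InferenceError, _effective_outcome

#: Cell area (um^2) assumed when masks are absent, a typical lymphocyte.
DEFAULT_CELL_AREA_UM2 = 50.0

FEATURE_NAMES: tuple[str, ...] = (
    "count_1", "count_2", "count_3", "count_4", "count_5",
    "prop_1", "prop_2", "prop_3", "prop_4", "prop_5",
    "size",
    "hull_area_um2",
    "density_per_um2",
    "ratio_B_T",
    "ratio_CD4_CD4neg",
    "ratio_lymph_DC",
    "mean_cell_area_um2",
    "sd_cell_area_um2",
    "mean_eccentricity",
    "hull_aspect_ratio",
    "hull_circularity",
    "max_pairwise_dist_um",
    "mean_nn_dist_um",
    "majority_prop",
)

#: Class-category membership per panel, used by ratios and rule classifiers.
_CATEGORIES = {
    "HR": {
        "B": ("B",),
        "T": ("CD4neg_T", "CD4pos_T"),
        "CD4pos": ("CD4pos_T",),
        "CD4neg": ("CD4neg_T",),
        "lymph": ("B", "CD4neg_T", "CD4pos_T"),
        "DC": ("pDC", "mDC"),
    },
    "HMP": {
        "B": ("B",),
        "T": ("CD4_T", "CD8_T", "DN_T"),
        "CD4pos": ("CD4_T",),
        "CD4neg": ("CD8_T", "DN_T"),
        "lymph": ("B", "CD4_T", "CD8_T", "DN_T", "plasma"),
        "DC": (),
    },
}


@dataclass(frozen=True)
class NeighborhoodParams:
    eps_px: float = 100.0  # HR default; use 50 for HMP sections
    min_size: int = 2

    def __post_init__(self) -> None:
        if self.eps_px <= 0 or self.min_size < 2:
            raise ValueError("eps_px must be > 0 and min_size >= 2")


@dataclass(frozen=True)
class RuleThresholds:
    bt_min_cells: int = 20          # inclusive
    bt_min_fraction: float = 0.50   # inclusive
    cd4neg_max_cells: int = 20      # exclusive
    cd4neg_min_fraction: float = 0.25  # inclusive


@dataclass
class Neighborhood:
    neigh_id: int
    roi_id: str
    member_ids: list[int]
    features: np.ndarray | None = None
    archetype: int | None = None
    rule_labels: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class KSelectionResult:
    k_grid: list[int]
    wcss: np.ndarray          # (n_boot, len(k_grid))
    mean_wcss: np.ndarray
    delta_wcss: np.ndarray    # mean WCSS(k_{i-1}) - WCSS(k_i), aligned to k_grid[1:]
    chosen_k: int


def detect_neighborhoods(cellmap: CellMap, params: NeighborhoodParams | None = None) -> list[Neighborhood]:
    """DBSCAN neighborhoods over centroids; isolated cells are noise."""
    params = params or NeighborhoodParams()
    if len(cellmap) == 0:
        return []
    xy = cellmap.centroids()
    labels = DBSCAN(eps=params.eps_px, min_samples=params.min_size).fit_predict(xy)
    ids = np.array([c.cell_id for c in cellmap.cells])
    out = []
    for lab in sorted(set(labels) - {-1}):
        members = sorted(int(i) for i in ids[labels == lab])
        if len(members) >= params.min_size:
            out.append(Neighborhood(neigh_id=int(lab), roi_id=cellmap.roi_id, member_ids=members))
    return out


def _panel_key(cellmap: CellMap) -> str:
    return "HR" if cellmap.frame.mode.value == "HR_ROI" else "HMP"


def _mask_shape_stats(cell, pixel_size_um: float) -> tuple[float, float]:
    """(area_um2, eccentricity) of one cell; defaults when the mask is absent."""
    if cell.mask is None or len(cell.mask) == 0:
        area = cell.area_px * pixel_size_um**2 if cell.area_px > 0 else DEFAULT_CELL_AREA_UM2
        return area, 0.0
    area = len(cell.mask) * pixel_size_um**2
    pts = cell.mask.astype(float)
    if len(pts) < 3:
        return area, 0.0
    cov = np.cov(pts.T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    if evals[1] <= 0:
        return area, 0.0
    ecc = float(np.sqrt(max(0.0, 1.0 - evals[0] / evals[1])))
    return area, ecc


def neighborhood_features(neigh: Neighborhood, cellmap: CellMap) -> np.ndarray:
    """The 24-feature vector of one neighborhood, in :data:`FEATURE_NAMES` order.

    Distances are in um and areas in um^2, so features are invariant under
    rigid translation and scale correctly with pixel size.  Degenerate
    hulls (collinear centroids) fall back to a 1-px-wide strip along the
    neighborhood diameter; all outputs are finite.
    """
    panel = cellmap.frame.panel
    cats = _CATEGORIES[_panel_key(cellmap)]
    ps = cellmap.frame.pixel_size_um
    by_id = {c.cell_id: c for c in cellmap.cells}
    members = [by_id[i] for i in neigh.member_ids]
    n = len(members)
    xy = np.array([[c.x, c.y] for c in members], dtype=float)

    counts = np.array([sum(c.base_class == cls for c in members) for cls in panel], dtype=float)
    props = counts / n

    def cat_count(name: str) -> float:
        return float(sum(counts[panel.index(cls)] for cls in cats[name]))

    # pairwise geometry (px), converted to um below
    d2 = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    np.fill_diagonal(d2, np.inf)
    max_pair_px = float(np.max(np.where(np.isinf(d2), 0.0, d2)))
    mean_nn_px = float(np.mean(np.min(d2, axis=1))) if n > 1 else 0.0

    hull_area_px2 = None
    hull_perim_px = None
    if n >= 3:
        try:
            hull = ConvexHull(xy)
            hull_area_px2 = float(hull.volume)
            hull_perim_px = float(hull.area)
        except QhullError:
            pass
    if not hull_area_px2:  # degenerate: 1-px strip along the diameter
        hull_area_px2 = max(max_pair_px, 1.0) * 1.0
        hull_perim_px = 2.0 * (max_pair_px + 1.0)
    hull_area_um2 = hull_area_px2 * ps**2
    circularity = 4.0 * np.pi * hull_area_px2 / hull_perim_px**2 if hull_perim_px else 0.0

    cov = np.cov(xy.T) if n > 1 else np.zeros((2, 2))
    evals = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))
    if evals[0] > 1e-12:
        aspect = float(np.sqrt(evals[1] / evals[0]))
    else:
        aspect = max(max_pair_px, 1.0)  # strip-like: diameter over 1 px

    shape_stats = [_mask_shape_stats(c, ps) for c in members]
    areas = np.array([s[0] for s in shape_stats])
    eccs = np.array([s[1] for s in shape_stats])

    feats = np.concatenate(
        [
            counts,
            props,
            [
                float(n),
                hull_area_um2,
                n / hull_area_um2,
                (cat_count("B") + 1.0) / (cat_count("T") + 1.0),
                (cat_count("CD4pos") + 1.0) / (cat_count("CD4neg") + 1.0),
                (cat_count("lymph") + 1.0) / (cat_count("DC") + 1.0),
                float(areas.mean()),
                float(areas.std()),
                float(eccs.mean()),
                aspect,
                circularity,
                max_pair_px * ps,
                mean_nn_px * ps,
                float(props.max()),
            ],
        ]
    )
    assert np.all(np.isfinite(feats))
    return feats


def featurize_cellmaps(
    cellmaps: list[CellMap], params: NeighborhoodParams | None = None
) -> tuple[pd.DataFrame, list[Neighborhood]]:
    """Detect and featurize neighborhoods across many ROIs/sections.

    Returns a feature table (one row per neighborhood, with ``roi_id`` and
    ``biopsy_id`` metadata) and the neighborhood objects with features
    attached.
    """
    rows = []
    all_neighs = []
    for m in cellmaps:
        for neigh in detect_neighborhoods(m, params):
            neigh.features = neighborhood_features(neigh, m)
            all_neighs.append(neigh)
            rows.append(
                {
                    "roi_id": m.roi_id,
                    "biopsy_id": m.biopsy_id,
                    "outcome": m.outcome.value,
                    **dict(zip(FEATURE_NAMES, neigh.features)),
                }
            )
    cols = ["roi_id", "biopsy_id", "outcome", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols), all_neighs


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def select_k_bootstrap_wcss(
    features: np.ndarray,
    k_grid: list[int] | None = None,
    n_boot: int = 10,
    seed: int = 0,
    elbow_fraction: float = 0.1,
    n_init: int = 4,
) -> KSelectionResult:
    """Choose the K-means class count by bootstrapped WCSS elbow.

    Per bootstrap replicate, rows are resampled with replacement, z-scored,
    and K-means is fit for every k in the grid.  The marginal decrement
    Delta WCSS(k) = WCSS(k-1) - WCSS(k), averaged over replicates, is
    compared to ``elbow_fraction`` of the k=1 WCSS; the chosen k is the one
    preceding the first k whose decrement falls below that threshold (the
    elbow), or the largest k when every decrement stays above it.
    """
    X = np.asarray(features, dtype=float)
    k_grid = sorted(k_grid or range(1, 11))
    if X.shape[0] < max(k_grid):
        raise InferenceError(f"need >= {max(k_grid)} rows, got {X.shape[0]}")
    rng = np.random.default_rng(seed)
    wcss = np.empty((n_boot, len(k_grid)))
    for b in range(n_boot):
        idx = rng.integers(0, X.shape[0], size=X.shape[0])
        Z = _zscore(X[idx])
        for j, k in enumerate(k_grid):
            km = KMeans(n_clusters=k, n_init=n_init, random_state=int(rng.integers(2**31)))
            km.fit(Z)
            wcss[b, j] = km.inertia_
    mean_wcss = wcss.mean(axis=0)
    delta = mean_wcss[:-1] - mean_wcss[1:]
    threshold = elbow_fraction * mean_wcss[0]
    chosen = k_grid[-1]
    for j, d in enumerate(delta):
        if d < threshold:
            chosen = k_grid[j]  # the k before the first small decrement
            break
    return KSelectionResult(
        k_grid=list(k_grid),
        wcss=wcss,
        mean_wcss=mean_wcss,
        delta_wcss=delta,
        chosen_k=int(chosen),
    )


def kmeans_neighborhood_classes(
    features: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """K-means archetypes over z-scored features; returns (labels, centroids).

    Centroids are reported in z-space.  Multiple restarts keep the best
    WCSS; deterministic under ``seed``.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < k:
        raise InferenceError(f"need >= {k} rows for k={k}")
    Z = _zscore(X)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(Z)
    return labels, km.cluster_centers_


def loo_feature_tests(features: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Leave-one-out Welch t statistics, archetype vs pooled rest.

    Returns a frame indexed by archetype label with one column per feature;
    positive entries mean the feature is elevated in that archetype.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    rows = {}
    for lab in sorted(set(labels.tolist())):
        in_g = labels == lab
        if in_g.sum() < 2 or (~in_g).sum() < 2:
            raise InferenceError(f"archetype {lab} has fewer than 2 members")
        t, _ = stats.ttest_ind(X[in_g], X[~in_g], equal_var=False)
        rows[lab] = t
    names = FEATURE_NAMES if X.shape[1] == len(FEATURE_NAMES) else range(X.shape[1])
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(names))


def top_features(test_matrix: pd.DataFrame, n: int = 1) -> dict:
    """Most elevated feature(s) per archetype (largest positive t)."""
    return {
        lab: list(test_matrix.loc[lab].sort_values(ascending=False).index[:n])
        for lab in test_matrix.index
    }


def classify_rule_based(
    size: int,
    class_counts: dict[str, int],
    thresholds: RuleThresholds | None = None,
    panel: str = "HR",
) -> set[str]:
    """Apply the B-T and CD4- rule classifiers to one neighborhood.

    ``class_counts`` maps panel class names to member counts.  The labels
    are independent: a neighborhood can satisfy neither.
    """
    th = thresholds or RuleThresholds()
    cats = _CATEGORIES[panel]
    b = sum(class_counts.get(c, 0) for c in cats["B"])
    cd4pos = sum(class_counts.get(c, 0) for c in cats["CD4pos"])
    cd4neg = sum(class_counts.get(c, 0) for c in cats["CD4neg"])
    labels: set[str] = set()
    if (
        size >= th.bt_min_cells
        and b >= 1
        and cd4pos >= 1
        and (b + cd4pos) / size >= th.bt_min_fraction
    ):
        labels.add("BT")
    if size < th.cd4neg_max_cells and cd4neg / size >= th.cd4neg_min_fraction:
        labels.add("CD4neg")
    return labels


def classify_neighborhood(
    neigh: Neighborhood,
    cellmap: CellMap,
    thresholds: RuleThresholds | None = None,
) -> set[str]:
    by_id = {c.cell_id: c for c in cellmap.cells}
    counts: dict[str, int] = {}
    for i in neigh.member_ids:
        counts[by_id[i].base_class] = counts.get(by_id[i].base_class, 0) + 1
    labels = classify_rule_based(neigh.size, counts, thresholds, panel=_panel_key(cellmap))
    neigh.rule_labels = labels
    return labels


def neighborhood_prevalence(
    labeled_counts: dict[str, int],
    cohort: CohortTable,
    groups: int = 2,
    family: int = 1,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-biopsy neighborhood prevalence and its cohort comparison.

    ``labeled_counts`` maps biopsy_id to the number of neighborhoods
    carrying the label of interest; biopsies absent from the dict count 0.
    Prevalence is normalized by the biopsy's ROI count.  Groups are
    compared by two-sided Mann-Whitney U with Bonferroni factor ``family``
    (the number of labels tested).
    """
    prev = {}
    for b, (outcome, n_rois, _) in cohort.entries.items():
        if n_rois == 0:
            raise InferenceError(f"{b}: n_rois is 0")
        prev[b] = labeled_counts.get(b, 0) / n_rois
    series = pd.Series(prev, name="per_roi_prevalence")

    group_of = {
        b: _effective_outcome(cohort.entries[b][0].value, groups) for b in cohort.entries
    }
    names = (
        [Outcome.ESRD_neg.value, Outcome.ESRD_pos.value]
        if groups == 2
        else [Outcome.ESRD_neg.value, Outcome.ESRD_pos.value, Outcome.ESRD_current.value]
    )
    rows = []
    for i, a in enumerate(names):
        for b_name in names[i + 1 :]:
            va = series[[b for b in series.index if group_of[b] == a]].to_numpy()
            vb = series[[b for b in series.index if group_of[b] == b_name]].to_numpy()
            if len(va) < 2 or len(vb) < 2:
                raise InferenceError("each group needs >= 2 biopsies")
            _, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            rows.append(
                {
                    "group_a": a,
                    "group_b": b_name,
                    "median_a": float(np.median(va)),
                    "median_b": float(np.median(vb)),
                    "p_raw": p,
                    "p_corrected": min(1.0, p * family),
                }
            )
    return series, pd.DataFrame(rows)
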