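"""Nearest-neighbor class analysis and cohort proportion tests.

For every cell in a frame the single closest other cell (Euclidean
centroid-to-centroid distance, ties broken by the lower cell id) is
recorded together with its class.  Frames are never pooled for the search:
nearest neighbors are found per ROI or per section.  Cohorts are compared
per source class by the chi-squared test of independence on the 2x2 table
(cohort x has-focal-class-neighbor), Bonferroni-corrected over source
classes.  No edge-effect buffering is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from lnspatial.core import CellMap


def nearest_neighbor_table(cellmap: CellMap) -> pd.DataFrame:
    """Nearest neighbor of every cell in one frame.

    Columns: cell_id, own class, neighbor cell_id, neighbor class, and
    distance in pixels.  A frame with fewer than two cells yields an empty
    table.
    """
    cols = ["cell_id", "base_class", "nn_cell_id", "nn_class", "distance_px"]
    if len(cellmap) < 2:
        return pd.DataFrame(columns=cols)
    xy = cellmap.centroids()
    ids = np.array([c.cell_id for c in cellmap.cells])
    classes = cellmap.classes()
    tree = cKDTree(xy)
    k = min(len(xy), 8)
    dists, idxs = tree.query(xy, k=k)
    rows = []
    for i in range(len(xy)):
        # drop self, then resolve distance ties by the lower cell_id
        cand = [(dists[i, j], idxs[i, j]) for j in range(k) if idxs[i, j] != i]
        dmin = min(c[0] for c in cand)
        tied = [j for d, j in cand if d <= dmin + 1e-9]
        j = min(tied, key=lambda j: ids[j])
        rows.append(
            {
                "cell_id": int(ids[i]),
                "base_class": classes[i],
                "nn_cell_id": int(ids[j]),
                "nn_class": classes[j],
                "distance_px": float(np.hypot(*(xy[i] - xy[j]))),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def pooled_nn_table(cellmaps: list[CellMap]) -> pd.DataFrame:
    """Concatenate per-frame nearest-neighbor tables (search stays per frame)."""
    parts = [nearest_neighbor_table(m).assign(roi_id=m.roi_id, outcome=m.outcome.value) for m in cellmaps]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


def chi2_independence(table_2x2: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared statistic and p for a 2x2 table (no Yates correction)."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table_2x2), correction=False)
    return float(chi2), float(p)


def nn_proportion_tests(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    focal_neighbor_class: str,
    cohort_names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Compare the share of cells whose nearest neighbor is the focal class.

    One chi-squared independence test per source class between the two
    cohorts' nearest-neighbor tables, Bonferroni-corrected over source
    classes.  Source classes missing from either cohort are skipped.
    """
    classes = sorted(set(table_a["base_class"]) | set(table_b["base_class"]))
    testable = [
        c
        for c in classes
        if (table_a["base_class"] == c).any() and (table_b["base_class"] == c).any()
    ]
    family = len(testable)
    rows = []
    for cls in classes:
        if cls not in testable:
            rows.append(
                {
                    "source_class": cls,
                    f"prop_{cohort_names[0]}": np.nan,
                    f"prop_{cohort_names[1]}": np.nan,
                    "chi2": np.nan,
                    "p_raw": np.nan,
                    "p_corrected": np.nan,
                    "skipped": True,
                }
            )
            continue
        sub_a = table_a[table_a["base_class"] == cls]
        sub_b = table_b[table_b["base_class"] == cls]
        hit_a = int((sub_a["nn_class"] == focal_neighbor_class).sum())
        hit_b = int((sub_b["nn_class"] == focal_neighbor_class).sum())
        cont = np.array(
            [[hit_a, len(sub_a) - hit_a], [hit_b, len(sub_b) - hit_b]], dtype=float
        )
        if (cont.sum(axis=0) == 0).any():
            chi2, p = np.nan, np.nan
        else:
            chi2, p = chi2_independence(cont)
        rows.append(
            {
                "source_class": cls,
                f"prop_{cohort_names[0]}": hit_a / len(sub_a),
                f"prop_{cohort_names[1]}": hit_b / len(sub_b),
                "chi2": chi2,
                "p_raw": p,
                "p_corrected": np.nan if np.isnan(p) else min(1.0, p * family),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)
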