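"""T-cell phenotyping: dual-round class combination and marker rules.

In the highly multiplexed dataset the three main T-cell classes are
obtained by combining detections from two staining rounds imaged at the
same tissue location — a CD3/CD4 round and a CD3/CD8 round: CD4+ cells,
CD8+ cells, and CD4-CD8- (DN) cells.  FoxP3 positivity is assigned from a
binary marker mask: a T cell is FoxP3+ when strictly more than 25% of its
mask pixels overlap the marker mask.

Phenotype rules over the resulting flags:

* Treg: CD4 T, FoxP3+ PD1- ICOS-
* exhausted CD8: CD8 T, PD1+ ICOS- FoxP3-
* Tfh (strict): CD4 T, PD1+ ICOS+ FoxP3-
* Tfh (expansive, default): CD4 T, PD1+ FoxP3- (ICOS either)

Labels are assigned under the precedence Treg > Tfh > exhausted, so no
cell carries two phenotype labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from lnspatial.core import CellMap, CellRecord


class TfhDefinition(str, enum.Enum):
    strict = "strict"
    expansive = "expansive"


@dataclass(frozen=True)
class PhenotypeParams:
    marker_overlap_fraction: float = 0.25  # strictly greater-than
    cross_round_iou: float = 0.25
    centroid_fallback_px: float = 5.0
    tfh_definition: TfhDefinition = TfhDefinition.expansive

    def __post_init__(self) -> None:
        if not 0 <= self.marker_overlap_fraction <= 1:
            raise ValueError("marker_overlap_fraction must lie in [0, 1]")


def assign_marker_positivity(cell: CellRecord, marker_mask, params: PhenotypeParams | None = None) -> bool:
    """True iff strictly more than the overlap fraction of the cell's mask
    lies inside the binary marker mask.

    ``marker_mask`` is a 2-D boolean array indexed ``[y, x]`` or a set of
    ``(x, y)`` pixels.
    """
    params = params or PhenotypeParams()
    if cell.mask is None:
        raise ValueError(f"cell {cell.cell_id} has no mask; overlap rule requires one")
    if isinstance(marker_mask, np.ndarray) and marker_mask.ndim == 2:
        xs, ys = cell.mask[:, 0], cell.mask[:, 1]
        inside = (ys >= 0) & (ys < marker_mask.shape[0]) & (xs >= 0) & (xs < marker_mask.shape[1])
        overlap = int(marker_mask[ys[inside], xs[inside]].sum())
    else:
        overlap = len(cell.mask_set & frozenset(map(tuple, marker_mask)))
    return overlap / len(cell.mask) > params.marker_overlap_fraction


def _match_rounds(a: CellMap, b: CellMap, params: PhenotypeParams) -> list[tuple[int, int]]:
    """One-to-one matching of cells across rounds.

    Pairs with mask IOU above the threshold are matched first (descending
    IOU); remaining cells fall back to centroid distance below the
    configured cutoff (ascending distance).  Ties break on ids.
    """
    candidates: list[tuple[float, int, int]] = []

    have_masks = all(c.mask is not None for c in a.cells + b.cells) and a.cells and b.cells
    if have_masks:
        for ca in a.cells:
            sa = ca.mask_set
            for cb in b.cells:
                sb = cb.mask_set
                union = len(sa | sb)
                iou = len(sa & sb) / union if union else 0.0
                if iou > params.cross_round_iou:
                    candidates.append((-iou, ca.cell_id, cb.cell_id))
    candidates.sort()
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, ia, ib in candidates:
        if ia in matched_a or ib in matched_b:
            continue
        matched_a.add(ia)
        matched_b.add(ib)
        pairs.append((ia, ib))

    # centroid-distance fallback for cells unmatched by IOU
    fallback: list[tuple[float, int, int]] = []
    for ca in a.cells:
        if ca.cell_id in matched_a:
            continue
        for cb in b.cells:
            if cb.cell_id in matched_b:
                continue
            d = float(np.hypot(ca.x - cb.x, ca.y - cb.y))
            if d <= params.centroid_fallback_px:
                fallback.append((d, ca.cell_id, cb.cell_id))
    fallback.sort()
    for _, ia, ib in fallback:
        if ia in matched_a or ib in matched_b:
            continue
        matched_a.add(ia)
        matched_b.add(ib)
        pairs.append((ia, ib))
    return pairs


def combine_tcell_rounds(
    cd4_round: CellMap, cd8_round: CellMap, params: PhenotypeParams | None = None
) -> CellMap:
    """Combine CD3/CD4-round and CD3/CD8-round detections into T-cell classes.

    Input cells must carry a ``base_class`` of ``"CD4_T"`` (double positive,
    CD3+CD4+) or ``"DN_T"`` (single positive, CD3+CD4-) in the CD4 round and
    ``"CD8_T"`` / ``"DN_T"`` analogously in the CD8 round.  Matched pairs
    resolve to CD4_T / CD8_T / DN_T; double positives (CD4+ and CD8+) are
    flagged ``phenotype="DP"`` and excluded from the three main classes;
    unmatched cells keep their single-round class.
    """
    params = params or PhenotypeParams()
    if cd4_round.frame != cd8_round.frame:
        raise ValueError("rounds must share a registered frame")

    a_by_id = {c.cell_id: c for c in cd4_round.cells}
    b_by_id = {c.cell_id: c for c in cd8_round.cells}
    pairs = _match_rounds(cd4_round, cd8_round, params)

    cells: list[CellRecord] = []
    next_id = 0
    used_a, used_b = set(), set()
    for ia, ib in pairs:
        ca, cb = a_by_id[ia], b_by_id[ib]
        used_a.add(ia)
        used_b.add(ib)
        cd4p = ca.base_class == "CD4_T"
        cd8p = cb.base_class == "CD8_T"
        if cd4p and cd8p:
            cls, pheno = "DN_T", "DP"  # base slot unused downstream; flagged DP
        elif cd4p:
            cls, pheno = "CD4_T", None
        elif cd8p:
            cls, pheno = "CD8_T", None
        else:
            cls, pheno = "DN_T", None
        cells.append(
            replace(
                ca,
                cell_id=next_id,
                base_class=cls,
                phenotype=pheno,
                markers=ca.markers | cb.markers,
            )
        )
        next_id += 1
    for c in cd4_round.cells:
        if c.cell_id not in used_a:
            cls = "CD4_T" if c.base_class == "CD4_T" else "DN_T"
            cells.append(replace(c, cell_id=next_id, base_class=cls))
            next_id += 1
    for c in cd8_round.cells:
        if c.cell_id not in used_b:
            cls = "CD8_T" if c.base_class == "CD8_T" else "DN_T"
            cells.append(replace(c, cell_id=next_id, base_class=cls))
            next_id += 1

    return CellMap(
        frame=cd4_round.frame,
        cells=cells,
        roi_id=cd4_round.roi_id,
        biopsy_id=cd4_round.biopsy_id,
        outcome=cd4_round.outcome,
        chronicity=cd4_round.chronicity,
    )


def label_tcell_phenotypes(cells: CellMap, params: PhenotypeParams | None = None) -> CellMap:
    """Attach Treg / Tfh / exhausted_CD8 phenotype labels from marker flags.

    Labels are mutually exclusive (precedence Treg > Tfh > exhausted) and
    every labeled cell keeps its base class.  Cells flagged ``DP`` by the
    round combiner are left untouched.
    """
    params = params or PhenotypeParams()
    out = cells.copy()
    for c in out.cells:
        if c.phenotype == "DP":
            continue
        pd1 = "PD1" in c.markers
        icos = "ICOS" in c.markers
        foxp3 = "FOXP3" in c.markers
        label = None
        if c.base_class == "CD4_T":
            if foxp3 and not pd1 and not icos:
                label = "Treg"
            elif pd1 and not foxp3:
                if params.tfh_definition is TfhDefinition.strict:
                    label = "Tfh" if icos else None
                else:
                    label = "Tfh"
        elif c.base_class == "CD8_T":
            if pd1 and not icos and not foxp3:
                label = "exhausted_CD8"
        c.phenotype = label
    return out
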