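"""Object-level evaluation of instance segmentations.

A predicted cell counts as a true positive when its mask has
intersection-over-union (IOU) greater than a threshold (default 0.25) with
an unmatched ground-truth cell of the same class, and its detection
confidence exceeds a threshold (default 0.3).  Predictions below the
confidence threshold are rejected before matching and generate no false
positive; remaining unmatched predictions are false positives and unmatched
truths are false negatives.  Because detection defines no true negatives,
performance is summarized by precision, recall, and F1:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with all three defined as 0 when their denominator is 0.  Matching is
greedy one-to-one in descending IOU order with ties broken by
``(pred_id, truth_id)``, which makes the result deterministic and
independent of input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lnspatial.core import CellMap


@dataclass(frozen=True)
class MatchParams:
    iou_threshold: float = 0.25
    confidence_threshold: float = 0.3
    require_class_match: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.iou_threshold <= 1 and 0 <= self.confidence_threshold <= 1):
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def metrics(self) -> tuple[float, float, float]:
        return detection_metrics((self.tp, self.fp, self.fn))


@dataclass
class MatchResult:
    tp_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    fp_ids: list[int] = field(default_factory=list)
    fn_ids: list[int] = field(default_factory=list)
    per_class: dict[str, ClassCounts] = field(default_factory=dict)

    @property
    def overall(self) -> ClassCounts:
        pooled = ClassCounts()
        for c in self.per_class.values():
            pooled.tp += c.tp
            pooled.fp += c.fp
            pooled.fn += c.fn
        return pooled


def mask_iou(mask_a, mask_b) -> float:
    """Intersection-over-union of two pixel sets.

    Accepts (n, 2) coordinate arrays or sets of pixel tuples; raises
    ``ValueError`` when both are empty (IOU is undefined, not 0).
    """
    a = frozenset(map(tuple, mask_a))
    b = frozenset(map(tuple, mask_b))
    union = len(a | b)
    if union == 0:
        raise ValueError("IOU of two empty masks is undefined")
    return len(a & b) / union


def detection_metrics(counts: tuple[int, int, int]) -> tuple[float, float, float]:
    """(precision, recall, F1) from (TP, FP, FN); zero denominators give 0."""
    tp, fp, fn = counts
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def match_detections(preds: CellMap, truths: CellMap, params: MatchParams | None = None) -> MatchResult:
    """Match predictions to ground truth and tally per-class TP/FP/FN.

    Requires masks on both maps and identical frames.  A prediction that
    overlaps a truth above the IOU threshold but disagrees in class is a
    false positive; the truth stays eligible for other predictions and
    becomes a false negative only if never matched.
    """
    params = params or MatchParams()
    if preds.frame != truths.frame:
        raise ValueError("prediction and truth maps must share a frame")

    kept = [p for p in preds.cells if p.confidence >= params.confidence_threshold]
    for cell in kept + truths.cells:
        if cell.mask is None:
            raise ValueError(f"cell {cell.cell_id} has no mask; matching requires masks")

    # bucket truth pixels for overlap candidate lookup
    pixel_owner: dict[tuple[int, int], list[int]] = {}
    truth_sets = {}
    for t in truths.cells:
        s = t.mask_set
        truth_sets[t.cell_id] = s
        for px in s:
            pixel_owner.setdefault(px, []).append(t.cell_id)

    truth_by_id = {t.cell_id: t for t in truths.cells}
    candidates: list[tuple[float, int, int]] = []
    for p in kept:
        pset = p.mask_set
        overlapping = {tid for px in pset for tid in pixel_owner.get(px, ())}
        for tid in overlapping:
            if params.require_class_match and truth_by_id[tid].base_class != p.base_class:
                continue
            tset = truth_sets[tid]
            iou = len(pset & tset) / len(pset | tset)
            if iou > params.iou_threshold:
                candidates.append((iou, p.cell_id, tid))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    matched_preds: set[int] = set()
    matched_truths: set[int] = set()
    result = MatchResult()
    for cls in truths.frame.panel:
        result.per_class[cls] = ClassCounts()

    for iou, pid, tid in candidates:
        if pid in matched_preds or tid in matched_truths:
            continue
        matched_preds.add(pid)
        matched_truths.add(tid)
        result.tp_pairs.append((pid, tid, iou))
        result.per_class[truth_by_id[tid].base_class].tp += 1

    for p in kept:
        if p.cell_id not in matched_preds:
            result.fp_ids.append(p.cell_id)
            result.per_class.setdefault(p.base_class, ClassCounts()).fp += 1
    for t in truths.cells:
        if t.cell_id not in matched_truths:
            result.fn_ids.append(t.cell_id)
            result.per_class[t.base_class].fn += 1

    result.tp_pairs.sort()
    result.fp_ids.sort()
    result.fn_ids.sort()
    return result
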