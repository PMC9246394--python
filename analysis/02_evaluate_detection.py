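"""Object-level detection evaluation on perturbed synthetic segmentations.

Degrades ground-truth cell maps with a known drop rate, spurious-detection
rate, and centroid jitter, then scores the perturbed "predictions" with the
IOU>0.25 / confidence>=0.3 matching protocol.  With a 20% drop rate the
measured recall should sit near 0.8 and precision near the kept/spurious
ratio.
"""

import argparse
from pathlib import Path

import pandas as pd

from lnspatial.segeval import detection_metrics, match_detections
from lnspatial.synth import PerturbSpec, SimConfig, generate_cohort, perturb_segmentation

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--drop", type=float, default=0.2)
    parser.add_argument("--spurious", type=float, default=0.1)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    cfg = SimConfig(
        n_esrd_neg=1, n_esrd_pos=0, n_esrd_current=0,
        rois_per_biopsy={"ESRD_neg": 13, "ESRD_pos": 1, "ESRD_current": 1},
        with_masks=True,
    )
    truths, _, _ = generate_cohort(cfg, args.seed)
    spec = PerturbSpec(drop_rate=args.drop, spurious_rate=args.spurious, jitter_px=1.0)

    per_class: dict[str, list[int]] = {}
    tp = fp = fn = 0
    for i, truth in enumerate(truths):
        pred = perturb_segmentation(truth, spec, seed=args.seed * 1000 + i)
        res = match_detections(pred, truth)
        for cls, c in res.per_class.items():
            agg = per_class.setdefault(cls, [0, 0, 0])
            agg[0] += c.tp
            agg[1] += c.fp
            agg[2] += c.fn
        o = res.overall
        tp, fp, fn = tp + o.tp, fp + o.fp, fn + o.fn

    rows = []
    for cls, (ctp, cfp, cfn) in per_class.items():
        p, r, f1 = detection_metrics((ctp, cfp, cfn))
        rows.append({"class": cls, "TP": ctp, "FP": cfp, "FN": cfn,
                     "precision": p, "recall": r, "f1": f1})
    p, r, f1 = detection_metrics((tp, fp, fn))
    rows.append({"class": "overall", "TP": tp, "FP": fp, "FN": fn,
                 "precision": p, "recall": r, "f1": f1})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "detection_metrics.csv", index=False)
    print(df.round(3).to_string(index=False))
    print(f"\ndrop rate {args.drop} -> recall {r:.3f} (expected ~{1-args.drop}); "
          f"wrote {RESULTS/'detection_metrics.csv'}")


if __name__ == "__main__":
    main()
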