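"""Cellular-neighborhood discovery, archetype classes, and cohort prevalence.

Detects DBSCAN neighborhoods (epsilon 100 px ~ 10.6 um, min size 2) across
the synthetic HR cohort, extracts the 24-feature description, selects the
number of K-means archetypes by bootstrapped WCSS, labels archetypes by
leave-one-out t tests, applies the B-T and CD4- rule classifiers, and
compares per-patient CD4- neighborhood prevalence between outcome groups.
"""

import argparse
from pathlib import Path

import pandas as pd

from lnspatial.density import per_roi_densities
from lnspatial.neighborhoods import (
    FEATURE_NAMES,
    classify_neighborhood,
    featurize_cellmaps,
    kmeans_neighborhood_classes,
    loo_feature_tests,
    neighborhood_prevalence,
    select_k_bootstrap_wcss,
    top_features,
)
from lnspatial.synth import SimConfig, generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--subsample-rois", type=int, default=250,
                        help="ROIs used for the feature/archetype analysis")
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    maps, cohort, _ = generate_cohort(SimConfig(), args.seed)

    # archetype discovery on a subset of ROIs (features are the slow part)
    sub = maps[: args.subsample_rois]
    feats, neighs = featurize_cellmaps(sub)
    X = feats[list(FEATURE_NAMES)].to_numpy()
    print(f"{len(feats)} neighborhoods featurized from {len(sub)} ROIs")

    ksel = select_k_bootstrap_wcss(X, list(range(1, 10)), n_boot=5, seed=args.seed)
    print(f"bootstrapped-WCSS k selection: chosen k = {ksel.chosen_k}")
    pd.DataFrame({"k": ksel.k_grid, "mean_wcss": ksel.mean_wcss}).to_csv(
        RESULTS / "k_selection.csv", index=False
    )

    k = max(ksel.chosen_k, 2)
    labels, _ = kmeans_neighborhood_classes(X, k, seed=args.seed)
    feats["archetype"] = labels
    loo = loo_feature_tests(X, labels)
    loo.to_csv(RESULTS / "archetype_feature_tests.csv")
    print("top distinguishing feature per archetype:",
          {a: f[0] for a, f in top_features(loo).items()})

    # rule classification + prevalence over the full cohort
    by_roi = {m.roi_id: m for m in maps}
    cd4neg_counts: dict[str, int] = {}
    bt_counts: dict[str, int] = {}
    n_neigh = 0
    from lnspatial.neighborhoods import detect_neighborhoods

    for m in maps:
        for neigh in detect_neighborhoods(m):
            n_neigh += 1
            rl = classify_neighborhood(neigh, m)
            if "CD4neg" in rl:
                cd4neg_counts[m.biopsy_id] = cd4neg_counts.get(m.biopsy_id, 0) + 1
            if "BT" in rl:
                bt_counts[m.biopsy_id] = bt_counts.get(m.biopsy_id, 0) + 1
    print(f"\n{n_neigh} neighborhoods across the full cohort "
          f"({sum(bt_counts.values())} B-T, {sum(cd4neg_counts.values())} CD4-)")

    prev, tests = neighborhood_prevalence(cd4neg_counts, cohort, groups=2, family=6)
    tests.to_csv(RESULTS / "cd4neg_prevalence_2group.csv", index=False)
    print("\nCD4- neighborhood prevalence, ESRD- vs ESRD+ (corrected):")
    print(tests.round(4).to_string(index=False))

    _, tests3 = neighborhood_prevalence(cd4neg_counts, cohort, groups=3, family=6)
    tests3.to_csv(RESULTS / "cd4neg_prevalence_3group.csv", index=False)
    feats.to_csv(RESULTS / "neighborhood_features.csv", index=False)
    print(f"\nwrote neighborhood tables under {RESULTS}")


if __name__ == "__main__":
    main()
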