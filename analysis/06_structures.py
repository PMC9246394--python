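"""Structure proximity: compartment areas and neighborhood-to-glomerulus
distances in whole-section (HMP-style) synthetic biopsies.

Generates sections with tubule/glomerulus layouts and periglomerular B-T
aggregates, measures compartment area fractions (TI > tubule > glomerulus),
computes minimum centroid-to-structure distances, and tests whether B-T
neighborhoods sit closer to glomeruli than other neighborhoods.
"""

import argparse
from pathlib import Path

import pandas as pd

from lnspatial.core import FrameMeta, Mode
from lnspatial.neighborhoods import NeighborhoodParams, classify_neighborhood, detect_neighborhoods
from lnspatial.structures import (
    cell_structure_distances,
    compare_rule_groups,
    compartment_areas,
    neighborhood_structure_distances,
)
from lnspatial.synth import (
    GLOMERULUS,
    TUBULE,
    SimConfig,
    StructureParams,
    _hmp_archetypes,
    generate_cohort,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    arch = _hmp_archetypes()
    arch["BT_large"].rates = {k: 80 for k in arch["BT_large"].rates}
    cfg = SimConfig(
        mode=Mode.HMP_SECTION,
        n_esrd_neg=6,
        n_esrd_pos=2,
        n_esrd_current=1,
        frame=FrameMeta(640, 640, 0.221, Mode.HMP_SECTION),
        archetypes=arch,
        structures=StructureParams(n_glomeruli=2, glomerulus_radius_px=(40, 55)),
    )
    maps, _, structs = generate_cohort(cfg, args.seed)

    area_rows, dist_parts = [], []
    for m in maps:
        smask = structs[m.roi_id]
        area_rows.append({"roi_id": m.roi_id, **compartment_areas(smask)})
        neighs = detect_neighborhoods(m, NeighborhoodParams(eps_px=50))
        for neigh in neighs:
            classify_neighborhood(neigh, m)
        for label, name in ((GLOMERULUS, "glom"), (TUBULE, "tubule")):
            cd = cell_structure_distances(m, smask, label)
            nd = neighborhood_structure_distances(neighs, cd)
            nd["target"] = name
            dist_parts.append(nd)

    areas = pd.DataFrame(area_rows)
    areas.to_csv(RESULTS / "compartment_areas.csv", index=False)
    print("compartment area fractions (mean over sections):")
    print(areas[["TI", "tubule", "glomerulus"]].mean().round(3).to_string())

    nd_all = pd.concat(dist_parts, ignore_index=True)
    nd_all.to_csv(RESULTS / "neighborhood_structure_distances.csv", index=False)
    for name in ("glom", "tubule"):
        sub = nd_all[nd_all.target == name]
        print(f"\nmedian neighborhood distance to {name} (um) by rule label:")
        print(sub.groupby("rule_label")["distance_um"].median().round(1).to_string())
        cmp_df = compare_rule_groups(sub)
        cmp_df.to_csv(RESULTS / f"neighborhood_{name}_comparison.csv", index=False)
        print(cmp_df.round(5).to_string(index=False))
    print(f"\nwrote structure-analysis tables under {RESULTS}")


if __name__ == "__main__":
    main()
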