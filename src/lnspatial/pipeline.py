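"""End-to-end orchestration of the synthetic-cohort analysis.

A run executes the enabled stages in dependency order — simulate,
detection evaluation, phenotyping, densities, neighborhoods, proximity,
structures — and writes one CSV table per stage into the run directory.
A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``, so toggling
one stage never shifts another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lnspatial.core import CellMap, CohortTable, Mode, Outcome
from lnspatial.density import (
    BootstrapParams,
    bootstrap_mean_difference,
    bootstrap_summary,
    cohort_density_comparison,
    per_roi_densities,
)
from lnspatial.neighborhoods import (
    NeighborhoodParams,
    RuleThresholds,
    classify_neighborhood,
    featurize_cellmaps,
    kmeans_neighborhood_classes,
    loo_feature_tests,
    neighborhood_prevalence,
    select_k_bootstrap_wcss,
    FEATURE_NAMES,
)
from lnspatial.proximity import nn_proportion_tests, pooled_nn_table
from lnspatial.segeval import MatchParams, match_detections
from lnspatial.structures import (
    cell_structure_distances,
    compare_rule_groups,
    compartment_areas,
    neighborhood_structure_distances,
)
from lnspatial.synth import (
    GLOMERULUS,
    PerturbSpec,
    SimConfig,
    generate_cohort,
    perturb_segmentation,
)

_STAGE_INDEX = {
    "simulate": 0,
    "eval_seg": 1,
    "phenotype": 2,
    "densities": 3,
    "neighborhoods": 4,
    "proximity": 5,
    "structures": 6,
}


def stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run_output"
    sim: SimConfig = field(default_factory=SimConfig)
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "eval_seg": True,
            "densities": True,
            "neighborhoods": True,
            "proximity": True,
            "structures": True,
        }
    )
    match_params: MatchParams = field(default_factory=MatchParams)
    perturb: PerturbSpec = field(
        default_factory=lambda: PerturbSpec(drop_rate=0.2, spurious_rate=0.1, jitter_px=1.0)
    )
    eval_n_rois: int = 3  # ROIs re-simulated with masks for the evaluation stage
    bootstrap: BootstrapParams = field(default_factory=BootstrapParams)
    neighborhood_params: NeighborhoodParams | None = None
    rule_thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    kmeans_k: int | None = None  # None -> bootstrapped-WCSS selection
    k_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load seed, output directory, stage toggles, and simple stage
        parameters from a YAML file; unspecified blocks keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "out_dir" in raw:
            cfg.out_dir = str(raw["out_dir"])
        if "stages" in raw:
            cfg.stages.update({k: bool(v) for k, v in raw["stages"].items()})
        if "mode" in raw:
            cfg.sim = SimConfig(mode=Mode(raw["mode"]))
        if "match" in raw:
            cfg.match_params = MatchParams(**raw["match"])
        if "perturb" in raw:
            cfg.perturb = PerturbSpec(**raw["perturb"])
        if "bootstrap" in raw:
            cfg.bootstrap = BootstrapParams(**raw["bootstrap"])
        if "neighborhoods" in raw:
            cfg.neighborhood_params = NeighborhoodParams(**raw["neighborhoods"])
        if "kmeans_k" in raw:
            cfg.kmeans_k = raw["kmeans_k"]
        return cfg

    def config_hash(self) -> str:
        blob = repr(
            (
                self.seed,
                sorted(self.stages.items()),
                self.match_params,
                self.perturb,
                self.bootstrap,
                self.neighborhood_params,
                self.rule_thresholds,
                self.kmeans_k,
                self.k_grid,
            )
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, out: Path, name: str, meta: dict) -> None:
    path = out / f"{name}.csv"
    with open(path, "w") as fh:
        fh.write(f"# config_hash={meta['config_hash']} seed={meta['seed']}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all enabled stages on a freshly simulated cohort."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    report = RunReport()
    report.summary["seed"] = config.seed
    report.summary["config_hash"] = meta["config_hash"]

    cellmaps, cohort, structures = generate_cohort(config.sim, stage_seed(config.seed, "simulate"))
    cohort_df = cohort.to_frame()
    report.tables["cohort"] = cohort_df
    _write(cohort_df, out, "cohort", meta)
    is_hmp = config.sim.mode is Mode.HMP_SECTION

    if config.stages.get("eval_seg", False):
        # separate masked truths so detection metrics reflect the configured
        # perturbation, not the main cohort (which skips masks for speed)
        eval_sim = SimConfig(
            mode=config.sim.mode,
            n_esrd_neg=1,
            n_esrd_pos=0,
            n_esrd_current=0,
            rois_per_biopsy={"ESRD_neg": config.eval_n_rois, "ESRD_pos": 1, "ESRD_current": 1},
            with_masks=True,
            structures=None,
        )
        seed = stage_seed(config.seed, "eval_seg")
        truths, _, _ = generate_cohort(eval_sim, seed)
        rows = []
        tp = fp = fn = 0
        for i, truth in enumerate(truths):
            preds = perturb_segmentation(truth, config.perturb, seed + i + 1)
            res = match_detections(preds, truth, config.match_params)
            o = res.overall
            tp, fp, fn = tp + o.tp, fp + o.fp, fn + o.fn
        from lnspatial.segeval import detection_metrics

        precision, recall, f1 = detection_metrics((tp, fp, fn))
        eval_df = pd.DataFrame(
            [{"TP": tp, "FP": fp, "FN": fn, "precision": precision, "recall": recall, "f1": f1}]
        )
        report.tables["detection_eval"] = eval_df
        _write(eval_df, out, "detection_eval", meta)
        report.summary["detection_f1"] = f1

    density_table = per_roi_densities(cellmaps)
    if config.stages.get("densities", False):
        comparison = cohort_density_comparison(density_table, cohort, groups=2)
        boot = bootstrap_mean_difference(
            density_table,
            cohort,
            BootstrapParams(
                n_iterations=config.bootstrap.n_iterations,
                sample_size_2group=config.bootstrap.sample_size_2group,
                sample_size_3group=config.bootstrap.sample_size_3group,
                ci_level=config.bootstrap.ci_level,
                seed=stage_seed(config.seed, "densities"),
            ),
            groups=2,
        )
        boot_df = bootstrap_summary(boot)
        report.tables["density_comparison"] = comparison
        report.tables["density_bootstrap"] = boot_df
        _write(comparison, out, "density_comparison", meta)
        _write(boot_df, out, "density_bootstrap", meta)

    neighs_by_map: dict[str, list] = {}
    if config.stages.get("neighborhoods", False):
        nparams = config.neighborhood_params or NeighborhoodParams(
            eps_px=50.0 if is_hmp else 100.0
        )
        feats_df, neighs = featurize_cellmaps(cellmaps, nparams)
        X = feats_df[list(FEATURE_NAMES)].to_numpy() if len(feats_df) else np.empty((0, 24))
        nseed = stage_seed(config.seed, "neighborhoods")
        if len(X) >= max(config.k_grid):
            if config.kmeans_k is None:
                ksel = select_k_bootstrap_wcss(X, list(config.k_grid), n_boot=5, seed=nseed)
                k = ksel.chosen_k
                report.summary["chosen_k"] = k
            else:
                k = config.kmeans_k
            if k >= 2:
                labels, _ = kmeans_neighborhood_classes(X, k, seed=nseed)
                feats_df["archetype"] = labels
                counts = np.bincount(labels)
                if counts.min() >= 2:  # LOO t tests need >= 2 members per archetype
                    loo = loo_feature_tests(X, labels)
                    report.tables["archetype_tests"] = loo.reset_index(names="archetype")
                    _write(report.tables["archetype_tests"], out, "archetype_tests", meta)
        by_roi = {m.roi_id: m for m in cellmaps}
        bt_counts: dict[str, int] = {}
        cd4neg_counts: dict[str, int] = {}
        for n in neighs:
            labels_ = classify_neighborhood(n, by_roi[n.roi_id], config.rule_thresholds)
            neighs_by_map.setdefault(n.roi_id, []).append(n)
            biopsy = by_roi[n.roi_id].biopsy_id
            if "BT" in labels_:
                bt_counts[biopsy] = bt_counts.get(biopsy, 0) + 1
            if "CD4neg" in labels_:
                cd4neg_counts[biopsy] = cd4neg_counts.get(biopsy, 0) + 1
        report.tables["neighborhoods"] = feats_df
        _write(feats_df, out, "neighborhoods", meta)
        prev, tests = neighborhood_prevalence(cd4neg_counts, cohort, groups=2, family=2)
        report.tables["cd4neg_prevalence_tests"] = tests
        _write(tests, out, "cd4neg_prevalence_tests", meta)
        report.summary["n_neighborhoods"] = len(neighs)

    if config.stages.get("proximity", False):
        neg = [m for m in cellmaps if m.outcome is Outcome.ESRD_neg]
        pos = [m for m in cellmaps if m.outcome in (Outcome.ESRD_pos, Outcome.ESRD_current)]
        if neg and pos:
            focal = "B"
            tests = nn_proportion_tests(
                pooled_nn_table(neg), pooled_nn_table(pos), focal, ("ESRD_neg", "ESRD_pos")
            )
            report.tables["nn_proportion_tests"] = tests
            _write(tests, out, "nn_proportion_tests", meta)

    if config.stages.get("structures", False) and structures:
        area_rows = []
        dist_parts = []
        by_roi = {m.roi_id: m for m in cellmaps}
        for roi_id, smask in structures.items():
            area_rows.append({"roi_id": roi_id, **compartment_areas(smask)})
            cd = cell_structure_distances(by_roi[roi_id], smask, GLOMERULUS)
            if roi_id in neighs_by_map:
                nd = neighborhood_structure_distances(neighs_by_map[roi_id], cd)
                dist_parts.append(nd)
        areas_df = pd.DataFrame(area_rows)
        report.tables["compartment_areas"] = areas_df
        _write(areas_df, out, "compartment_areas", meta)
        if dist_parts:
            nd_all = pd.concat(dist_parts, ignore_index=True)
            report.tables["neighborhood_glom_distances"] = nd_all
            _write(nd_all, out, "neighborhood_glom_distances", meta)
            cmp_df = compare_rule_groups(nd_all)
            report.tables["neighborhood_glom_comparison"] = cmp_df
            _write(cmp_df, out, "neighborhood_glom_comparison", meta)

    (out / "summary.json").write_text(json.dumps(report.summary, indent=2, default=str))
    return report
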