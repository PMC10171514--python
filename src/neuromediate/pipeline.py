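"""End-to-end study orchestration.

Runs, on a simulated or loaded cohort: per-stream outlier exclusion (3-IQR
rule on the intelligence score and the global brain metrics), group
Holm-Bonferroni pruning of each connectome modality, per-subject shortest-path
efficiency, hemisphere averaging, global single-mediator mediation for every
PGS x whole-brain metric, regularized multi-mediator mediation for every PGS x
regional metric family, optional combined all-metrics model, and P-FIT
annotation of the selected mediators.  Everything is deterministic given the
master seed, which fans out to named sub-seeds recorded in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas, connectome, mediation, stats, synthetic

logger = logging.getLogger(__name__)

GLOBAL_METRICS = ("total_surface_area", "mean_thickness", "structural_E", "functional_E")
FAMILIES = ("surface_area", "thickness", "structural_efficiency", "functional_efficiency")
_FAMILY_STREAM = {
    "surface_area": "anatomical",
    "thickness": "anatomical",
    "structural_efficiency": "structural",
    "functional_efficiency": "functional",
}
_METRIC_STREAM = {
    "total_surface_area": "anatomical",
    "mean_thickness": "anatomical",
    "structural_E": "structural",
    "functional_E": "functional",
}


@dataclass
class RunConfig:
    """Structured configuration of a full study run."""

    mode: str = "simulate"  # or "load"
    input_dir: str | None = None
    output_dir: str | None = None
    master_seed: int = 0
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    prune: connectome.PruneConfig = field(default_factory=connectome.PruneConfig)
    mediation: mediation.RegularizedMediationConfig = field(
        default_factory=mediation.RegularizedMediationConfig
    )
    covariates: tuple[str, ...] = ("age", "sex", "pc1", "pc2", "pc3", "pc4")
    pgs_list: tuple[str, ...] = ("EA", "GI")
    metric_families: tuple[str, ...] = FAMILIES
    include_combined: bool = False
    annotate_pfit: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.mode == "load" and not self.input_dir:
            raise ValueError("load mode requires input_dir")
        if not self.metric_families:
            raise ValueError("model roster must not be empty")
        # the master seed fans out to the generator and the CV folds
        self.cohort = dataclasses.replace(self.cohort, seed=self.master_seed)
        self.mediation = dataclasses.replace(
            self.mediation, cv_seed=(self.master_seed * 1000 + 1) % (2**31)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "cohort" in kw:
            ck = dict(kw["cohort"])
            if "true_mediators" in ck and ck["true_mediators"] is not None:
                ck["true_mediators"] = [
                    synthetic.TrueMediator(**m) for m in ck["true_mediators"]
                ]
            if "edge_weight_model" in ck:
                ck["edge_weight_model"] = synthetic.EdgeWeightModel(**ck["edge_weight_model"])
            if "functional_noise" in ck:
                ck["functional_noise"] = synthetic.FunctionalModel(**ck["functional_noise"])
            kw["cohort"] = synthetic.CohortConfig(**ck)
        if "prune" in kw:
            kw["prune"] = connectome.PruneConfig(**kw["prune"])
        if "mediation" in kw:
            kw["mediation"] = mediation.RegularizedMediationConfig(**kw["mediation"])
        for key in ("covariates", "pgs_list", "metric_families"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


@dataclass
class StudyReport:
    """All results of one pipeline run, JSON-serializable."""

    seeds: dict
    exclusions: dict  # stream -> {excluded: [...], remaining_n: int}
    network: dict  # modality -> {removed_edges, removed_nodes, iterations, retained_edges}
    candidate_counts: dict  # family -> int
    global_models: list  # dicts: pgs, metric, paths...
    regional_models: list  # dicts: pgs, family, n_candidates, selected, refit, pfit
    combined_model: dict | None
    recovery: dict | None  # selection metrics vs ground truth, if available

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "StudyReport":
        return cls(**json.loads(Path(path).read_text()))


def _standardize_residualize(values: np.ndarray, cov: np.ndarray) -> np.ndarray:
    return stats.residualize(values, cov, standardize=True)


def _paths_dict(p: mediation.MediationPaths) -> dict:
    return {
        "a": p.a, "b": p.b, "c_prime": p.c_prime, "indirect": p.indirect,
        "total": p.total, "se": p.se, "p": p.p, "n": p.n,
    }


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute the full study; see the module docstring for the stage order."""
    # ---- cohort -----------------------------------------------------------
    truth = None
    if config.mode == "simulate":
        cohort, truth = synthetic.generate_cohort(config.cohort)
    else:
        cohort, truth = synthetic.load_cohort(config.input_dir)
    pheno = cohort.phenotypes.reset_index(drop=True)
    subjects = pheno["subject"].astype(str).tolist()

    # ---- networks: prune, efficiency, hemisphere averaging ---------------
    network_info: dict[str, dict] = {}
    nodal_regions: dict[str, pd.DataFrame] = {}
    global_eff: dict[str, pd.Series] = {}
    for modality, group in (("structural", cohort.structural), ("functional", cohort.functional)):
        if group is None:
            continue
        if group.n_subjects < 2:
            raise ValueError(f"{modality}: group pruning needs at least 2 subjects")
        mask, pruned = connectome.holm_prune(group, config.prune)
        nodal, glob = connectome.group_efficiency(
            pruned, clip_negative=(modality == "functional")
        )
        nodal_regions[modality] = connectome.average_hemispheres(nodal)
        global_eff[modality] = glob
        network_info[modality] = {
            "removed_edges": mask.removed_edges,
            "retained_edges": mask.retained_edges(),
            "removed_nodes": mask.removed_nodes,
            "iterations": mask.iterations,
            "n_nodes_after": pruned.n_nodes,
        }

    # ---- global metric table ---------------------------------------------
    table = pheno.copy()
    region_cols = cohort.surface_area.columns[1:]
    table["total_surface_area"] = cohort.surface_area[region_cols].sum(axis=1).to_numpy()
    table["mean_thickness"] = cohort.thickness[region_cols].mean(axis=1).to_numpy()
    if "structural" in global_eff:
        table["structural_E"] = global_eff["structural"].reindex(subjects).to_numpy()
    if "functional" in global_eff:
        table["functional_E"] = global_eff["functional"].reindex(subjects).to_numpy()

    # ---- per-stream outlier exclusion ------------------------------------
    streams = {"anatomical": ["iq", "total_surface_area", "mean_thickness"]}
    if "structural_E" in table:
        streams["structural"] = ["iq", "structural_E"]
    if "functional_E" in table:
        streams["functional"] = ["iq", "functional_E"]
    report_outliers = stats.stream_outliers(table, streams)
    keep_idx: dict[str, np.ndarray] = {}
    exclusions = {}
    for stream, excluded in report_outliers.excluded.items():
        keep = ~table["subject"].astype(str).isin(excluded)
        keep_idx[stream] = keep.to_numpy()
        exclusions[stream] = {"excluded": excluded, "remaining_n": int(keep.sum())}
        logger.info("stream %s: excluded %d subjects, %d remain",
                    stream, len(excluded), int(keep.sum()))

    # ---- global mediation models -----------------------------------------
    pgs_cols = {"EA": "pgs_ea", "GI": "pgs_gi"}
    cov_all = table[list(config.covariates)].to_numpy(dtype=float)
    global_models = []
    for pgs in config.pgs_list:
        for metric in GLOBAL_METRICS:
            if metric not in table:
                continue
            keep = keep_idx.get(_METRIC_STREAM[metric])
            if keep is None:
                continue
            paths = mediation.mediate_single(
                table.loc[keep, pgs_cols[pgs]].to_numpy(dtype=float),
                table.loc[keep, metric].to_numpy(dtype=float),
                table.loc[keep, "iq"].to_numpy(dtype=float),
                covariates=cov_all[keep],
            )
            global_models.append({"pgs": pgs, "metric": metric, **_paths_dict(paths)})

    # ---- regional candidate tables ---------------------------------------
    family_tables: dict[str, pd.DataFrame] = {}
    if "surface_area" in config.metric_families:
        family_tables["surface_area"] = cohort.surface_area.set_index("subject")
    if "thickness" in config.metric_families:
        family_tables["thickness"] = cohort.thickness.set_index("subject")
    if "structural_efficiency" in config.metric_families and "structural" in nodal_regions:
        df = nodal_regions["structural"]
        df.index = subjects
        family_tables["structural_efficiency"] = df
    if "functional_efficiency" in config.metric_families and "functional" in nodal_regions:
        df = nodal_regions["functional"]
        df.index = subjects
        family_tables["functional_efficiency"] = df
    candidate_counts = {fam: int(df.shape[1]) for fam, df in family_tables.items()}

    pfit = None
    if config.annotate_pfit:
        cortical = [c for c in region_cols]
        pfit = atlas.pfit_membership(cortical, seed=config.master_seed)

    # ---- regularized regional mediation ----------------------------------
    regional_models = []

    def run_regional(pgs: str, fam: str, df: pd.DataFrame, keep: np.ndarray) -> dict:
        sub = table.loc[keep]
        cov = cov_all[keep]
        x = _standardize_residualize(sub[pgs_cols[pgs]].to_numpy(dtype=float), cov)
        y = _standardize_residualize(sub["iq"].to_numpy(dtype=float), cov)
        vals = df.loc[sub["subject"].astype(str)].to_numpy(dtype=float)
        M = np.column_stack(
            [_standardize_residualize(vals[:, j], cov) for j in range(vals.shape[1])]
        )
        res = mediation.regularized_mediation(
            x, M, y, config.mediation, mediator_ids=list(df.columns)
        )
        entry = {
            "pgs": pgs,
            "family": fam,
            "n": res.n,
            "n_candidates": len(res.mediator_ids),
            "selected": res.selected,
            "a_nonzero": res.a_nonzero,
            "b_nonzero": res.b_nonzero,
            "penalty_a": res.penalty_a,
            "penalty_b": res.penalty_b,
            "c_prime_penalized": res.c_prime_penalized,
            "refit": None,
            "pfit": None,
        }
        if res.refit is not None:
            entry["refit"] = {
                "c_prime": res.refit.c_prime,
                "paths": {k: _paths_dict(v) for k, v in res.refit.paths.items()},
            }
        if pfit is not None:
            entry["pfit"] = {
                r: bool(pfit[r]) if r in pfit.index else None for r in res.selected
            }
        return entry

    for pgs in config.pgs_list:
        for fam in config.metric_families:
            if fam not in family_tables:
                continue
            keep = keep_idx.get(_FAMILY_STREAM[fam])
            if keep is None:
                continue
            regional_models.append(run_regional(pgs, fam, family_tables[fam], keep))

    # ---- optional combined all-metrics model -----------------------------
    combined = None
    if config.include_combined and family_tables:
        keep = np.logical_and.reduce([keep_idx[s] for s in keep_idx])
        pooled = pd.concat(
            {fam: df for fam, df in family_tables.items()}, axis=1
        )
        pooled.columns = [f"{fam}:{region}" for fam, region in pooled.columns]
        logger.info("combined model pools %d candidate mediators", pooled.shape[1])
        combined_entries = []
        for pgs in config.pgs_list:
            entry = run_regional(pgs, "combined", pooled, keep)
            combined_entries.append(entry)
        combined = {"n_candidates": int(pooled.shape[1]), "models": combined_entries}

    # ---- recovery vs ground truth ----------------------------------------
    recovery = None
    if truth is not None:
        recovery = {}
        union_selected: set[tuple[str, str]] = set()
        union_candidates: set[tuple[str, str]] = set()
        for entry in regional_models:
            fam = entry["family"]
            df = family_tables[fam]
            truth_ids = truth.true_mediator_ids(fam, pgs=entry["pgs"])
            key = f"{entry['pgs']}:{fam}"
            recovery[key] = mediation.selection_metrics(
                entry["selected"], truth_ids, list(df.columns)
            )
            union_selected |= {(fam, r) for r in entry["selected"]}
            union_candidates |= {(fam, r) for r in df.columns}
        all_truth = [
            (m["modality"], m["region"])
            for m in truth.mediators
            if m["modality"] in family_tables
        ]
        recovery["overall"] = mediation.selection_metrics(
            [f"{f}:{r}" for f, r in union_selected],
            [f"{f}:{r}" for f, r in all_truth],
            [f"{f}:{r}" for f, r in union_candidates],
        )

    return StudyReport(
        seeds={
            "master_seed": config.master_seed,
            "cohort_seed": config.cohort.seed,
            "cv_seed": config.mediation.cv_seed,
        },
        exclusions=exclusions,
        network=network_info,
        candidate_counts=candidate_counts,
        global_models=global_models,
        regional_models=regional_models,
        combined_model=combined,
        recovery=recovery,
    )


def write_report(report: StudyReport, out_dir) -> list[Path]:
    """Write the JSON manifest, TSV tables and a human-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = [out / "report.json"]
    report.to_json(out / "report.json")

    rows = []
    for entry in report.regional_models:
        refit = entry.get("refit") or {"paths": {}}
        for region in entry["selected"]:
            paths = refit["paths"].get(region, {})
            rows.append(
                {
                    "pgs": entry["pgs"],
                    "family": entry["family"],
                    "region": region,
                    "refit_a": paths.get("a"),
                    "refit_b": paths.get("b"),
                    "refit_indirect": paths.get("indirect"),
                    "pfit": (entry.get("pfit") or {}).get(region),
                }
            )
    mediators = pd.DataFrame(
        rows, columns=["pgs", "family", "region", "refit_a", "refit_b",
                       "refit_indirect", "pfit"]
    )
    mediators.to_csv(out / "selected_mediators.tsv", sep="\t", index=False)
    written.append(out / "selected_mediators.tsv")

    glob = pd.DataFrame(
        [
            {k: m[k] for k in ("pgs", "metric", "a", "b", "c_prime", "indirect", "total")}
            for m in report.global_models
        ]
    )
    glob.to_csv(out / "global_models.tsv", sep="\t", index=False)
    written.append(out / "global_models.tsv")

    lines = ["study report", "============", ""]
    for stream, info in report.exclusions.items():
        lines.append(
            f"{stream}: excluded {len(info['excluded'])}, remaining n = {info['remaining_n']}"
        )
    for modality, info in report.network.items():
        lines.append(
            f"{modality} network: removed {info['removed_edges']} edges, "
            f"{len(info['removed_nodes'])} nodes; {info['n_nodes_after']} nodes remain"
        )
    for fam, cnt in report.candidate_counts.items():
        lines.append(f"{fam}: {cnt} candidate mediators")
    for entry in report.regional_models:
        lines.append(
            f"{entry['pgs']} x {entry['family']}: selected {len(entry['selected'])} "
            f"mediators: {', '.join(entry['selected']) or '(none)'}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    written.append(out / "summary.txt")
    return written
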