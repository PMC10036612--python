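"""Pipeline orchestration: simulate -> famrs -> pgs -> analyze -> reclass -> report.

Each stage reads/writes plain TSV (plus one VCF and one scoring file),
so any stage can also be run standalone on real data in the same
dialects.  A manifest (JSON) records the seed, package version and
sha256 of every output, making end-to-end runs reproducible and
byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, discrimination, famrs as famrs_mod, io as kio, models, pgs as pgs_mod
from .simulate import SimulationConfig, simulate_cohort, write_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "famrs", "pgs", "analyze", "reclass", "report")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    famrs: famrs_mod.FamRSConfig = field(default_factory=famrs_mod.FamRSConfig)
    pgs_missing_policy: str = "zero"
    pgs_keep_ambiguous: bool = False
    top_percentiles: tuple = (20, 10, 5)
    min_stratum_events: int = 10
    ipcw_method: str = "cox"
    log_level: str = "INFO"

    def validate(self) -> None:
        self.simulation.validate()
        self.famrs.validate()
        if self.pgs_missing_policy not in ("zero", "mean_impute", "require_any"):
            raise ValueError(f"unknown pgs_missing_policy {self.pgs_missing_policy!r}")
        if self.ipcw_method not in ("cox", "kaplan_meier"):
            raise ValueError(f"unknown ipcw_method {self.ipcw_method!r}")


def config_from_yaml(path) -> PipelineConfig:
    """Load a PipelineConfig from YAML; every sub-config field addressable."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimulationConfig(**(raw.get("simulation") or {}))
    fam_raw = dict(raw.get("famrs") or {})
    if "expected_risk_table" in fam_raw:
        fam_raw["expected_risk_table"] = {
            (int(k.split("/")[0]), k.split("/")[1]): float(v)
            for k, v in fam_raw["expected_risk_table"].items()
        }
    if "category_cuts" in fam_raw:
        fam_raw["category_cuts"] = tuple(fam_raw["category_cuts"])
    fam = famrs_mod.FamRSConfig(**fam_raw)
    other = {
        k: v for k, v in raw.items() if k not in ("simulation", "famrs")
    }
    if "top_percentiles" in other:
        other["top_percentiles"] = tuple(other["top_percentiles"])
    cfg = PipelineConfig(simulation=sim, famrs=fam, **other)
    cfg.validate()
    return cfg


def config_to_yaml(config: PipelineConfig, path) -> None:
    sim = dataclasses.asdict(config.simulation)
    for k, v in sim.items():
        if isinstance(v, np.ndarray):
            sim[k] = [float(x) for x in v]
    fam = {
        "onset_weight": dict(config.famrs.onset_weight),
        "expected_risk_table": {
            f"{b}/{rel}": float(e)
            for (b, rel), e in config.famrs.expected_risk_table.items()
        },
        "category_cuts": list(config.famrs.category_cuts),
    }
    doc = {
        "simulation": sim,
        "famrs": fam,
        "pgs_missing_policy": config.pgs_missing_policy,
        "pgs_keep_ambiguous": config.pgs_keep_ambiguous,
        "top_percentiles": list(config.top_percentiles),
        "min_stratum_events": config.min_stratum_events,
        "ipcw_method": config.ipcw_method,
        "log_level": config.log_level,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class CohortSummary:
    """Baseline table of the analysis cohort (percentages against full n)."""

    n: int
    percent_female: float
    age_mean: float
    age_sd: float
    age_quartiles: tuple
    bmi_mean: float
    bmi_sd: float
    percent_active: float
    famrs_category_counts: dict
    n_prevalent: int
    percent_prevalent: float
    n_incident: int
    percent_incident: float
    person_years: float
    median_followup: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_quartiles"] = list(self.age_quartiles)
        return d


def summarize_cohort(cohort: pd.DataFrame, famrs: pd.DataFrame | None = None) -> CohortSummary:
    """Descriptive statistics; incident percentage uses the full-cohort
    denominator (not the incident risk set)."""
    if cohort.empty:
        raise ValueError("cannot summarise an empty cohort")
    n = len(cohort)
    cat_counts: dict = {}
    if famrs is not None:
        cat_counts = famrs["category"].value_counts().to_dict()
    n_prev = int(cohort["t2d_prevalent"].sum())
    n_inc = int(cohort["t2d_incident"].sum())
    return CohortSummary(
        n=n,
        percent_female=100.0 * (cohort["sex"] == "F").mean(),
        age_mean=float(cohort["age_baseline"].mean()),
        age_sd=float(cohort["age_baseline"].std(ddof=1)),
        age_quartiles=tuple(
            float(q) for q in cohort["age_baseline"].quantile([0.25, 0.5, 0.75])
        ),
        bmi_mean=float(cohort["bmi"].mean()),
        bmi_sd=float(cohort["bmi"].std(ddof=1)),
        percent_active=100.0 * cohort["physical_activity"].mean(),
        famrs_category_counts=cat_counts,
        n_prevalent=n_prev,
        percent_prevalent=100.0 * n_prev / n,
        n_incident=n_inc,
        percent_incident=100.0 * n_inc / n,
        person_years=float(cohort["followup_time"].sum()),
        median_followup=float(cohort["followup_time"].median()),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


@_stage("simulate")
def stage_simulate(config: PipelineConfig, seed: int, out: Path) -> dict:
    cohort = simulate_cohort(config.simulation, seed=seed)
    return write_cohort(cohort, out)


@_stage("famrs")
def stage_famrs(config: PipelineConfig, out: Path, cohort_path, famhist_path) -> str:
    cohort = kio.read_cohort_table(cohort_path)
    fh = kio.read_family_history(famhist_path)
    ages = cohort.set_index("person_id")["age_baseline"]
    table = famrs_mod.compute_famrs_table(fh, ages, config.famrs)
    path = out / "famrs.tsv"
    table.assign(parental_history=table["parental_history"].astype(int)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return str(path)


@_stage("pgs")
def stage_pgs(config: PipelineConfig, out: Path, vcf_path, scoring_path) -> str:
    scores, report = pgs_mod.score_vcf(
        vcf_path,
        scoring_path,
        missing_policy=config.pgs_missing_policy,
        keep_ambiguous=config.pgs_keep_ambiguous,
    )
    log.info(
        "pgs: %d/%d variants matched (%d ambiguous excluded, %d unmatched)",
        report.n_matched, report.n_panel,
        len(report.excluded_ambiguous), len(report.unmatched),
    )
    path = out / "pgs.tsv"
    cols = ["person_id", "raw_score", "z_score", "percentile_group",
            "n_matched", "n_missing", "top20", "top10", "top5", "top1"]
    o = scores[cols].copy()
    for q in (20, 10, 5, 1):
        o[f"top{q}"] = o[f"top{q}"].astype(int)
    o.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return str(path)


def _read_scores(famrs_path, pgs_path):
    fam = pd.read_csv(famrs_path, sep="\t", dtype={"person_id": str})
    fam["parental_history"] = fam["parental_history"].astype(bool)
    pg = pd.read_csv(pgs_path, sep="\t", dtype={"person_id": str})
    for q in (20, 10, 5, 1):
        pg[f"top{q}"] = pg[f"top{q}"].astype(bool)
    return fam, pg


@_stage("analyze")
def stage_analyze(config: PipelineConfig, out: Path, cohort_path, famrs_path, pgs_path) -> dict:
    cohort = kio.read_cohort_table(cohort_path)
    fam, pg = _read_scores(famrs_path, pgs_path)
    grid = models.run_model_grid(cohort, fam, pg, ipcw_method=config.ipcw_method)
    top = models.top_percentile_models(
        cohort, fam, pg, quantiles=config.top_percentiles, ipcw_method=config.ipcw_method
    )
    strata = models.age_stratified_models(
        cohort, fam, pg, min_events=config.min_stratum_events,
        ipcw_method=config.ipcw_method,
    )
    paths = {}
    for name, df in (
        ("results_main", grid),
        ("results_top_percentiles", top),
        ("results_age_strata", strata),
    ):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        paths[name] = str(p)
    return paths


@_stage("reclass")
def stage_reclass(config: PipelineConfig, out: Path, cohort_path, famrs_path, pgs_path) -> str:
    cohort = kio.read_cohort_table(cohort_path)
    fam, pg = _read_scores(famrs_path, pgs_path)
    df = models.build_analysis_frame(cohort, fam, pg)
    y = df["t2d_prevalent"].astype(int).to_numpy()
    base = list(models.BASE_COVARIATES)
    p_old = models.predicted_probabilities(df[base], y)
    p_new = models.predicted_probabilities(df[base + ["pgs_z", "famrs2", "famrs3"]], y)
    rec = discrimination.reclassification(p_old, p_new, y.astype(bool))
    roc_pgs = discrimination.roc_auc(df["pgs_raw"], y.astype(bool))
    roc_fam = discrimination.roc_auc(df["famrs_score"], y.astype(bool))
    corr = discrimination.spearman(df["famrs_score"], df["pgs_raw"])
    doc = {
        "outcome": "prevalent",
        "added_predictors": ["pgs_z", "famrs2", "famrs3"],
        "reclassification": dataclasses.asdict(rec),
        "roc": {
            "pgs": {
                "auc": roc_pgs.auc,
                "best_threshold": roc_pgs.best_threshold,
                "sensitivity": roc_pgs.sensitivity,
                "specificity": roc_pgs.specificity,
            },
            "famrs": {
                "auc": roc_fam.auc,
                "best_threshold": roc_fam.best_threshold,
                "sensitivity": roc_fam.sensitivity,
                "specificity": roc_fam.specificity,
            },
        },
        "famrs_pgs_spearman": dataclasses.asdict(corr),
    }
    path = out / "reclassification.json"
    path.write_text(json.dumps(doc, indent=2))
    return str(path)


@_stage("report")
def stage_report(config: PipelineConfig, out: Path, cohort_path, famrs_path) -> str:
    cohort = kio.read_cohort_table(cohort_path)
    fam, _ = pd.read_csv(famrs_path, sep="\t", dtype={"person_id": str}), None
    summary = summarize_cohort(cohort, fam)
    path = out / "cohort_summary.json"
    path.write_text(json.dumps(summary.to_dict(), indent=2))
    return str(path)


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0, out_dir=".") -> dict:
    """Run all stages under one seed; return (and write) the manifest."""
    config = config or PipelineConfig()
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = dict(stage_simulate(config, seed, out))
    files["famrs"] = stage_famrs(config, out, files["cohort"], files["family_history"])
    files["pgs"] = stage_pgs(config, out, files["vcf"], files["scoring_file"])
    files.update(stage_analyze(config, out, files["cohort"], files["famrs"], files["pgs"]))
    files["reclassification"] = stage_reclass(
        config, out, files["cohort"], files["famrs"], files["pgs"]
    )
    files["cohort_summary"] = stage_report(config, out, files["cohort"], files["famrs"])
    manifest = {
        "kinrisk_version": __version__,
        "seed": seed,
        "files": {k: {"path": v, "sha256": _sha256(Path(v))} for k, v in files.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
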