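"""Run configuration and end-to-end pipeline orchestration.

Stages run strictly in order: reduce -> mirv -> response -> association ->
survival. Any stage failure aborts with a stage-named error; stages whose
inputs are absent (no clinical table, single-class endpoint) are skipped
with a logged notice rather than failing the run.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    baseline_volume_metrics,
    compare_auc,
    fit_cv_logistic,
    ordinal_encode,
    spearman_matrix,
)
from .errors import ConfigError, StageError
from .io import (
    BASELINE,
    FOLLOWUP,
    TableSchema,
    clinical_frame,
    config_hash,
    read_clinical_table,
    read_feature_table,
    write_results,
)
from .metrics import AGGREGATORS, compute_mirv, zscore_features
from .reduction import reduce_features
from .response import compute_response
from .survival import fit_cox, km_logrank_subgroups, subgroup_frame

RECIST_ORDER = {"CR": 0, "PR": 1, "SD": 2, "PD": 3}


@dataclass
class RunConfig:
    """Validated run configuration; every threshold is echoed to the run log."""

    feature_table: str = ""
    clinical_table: str = ""
    out_dir: str = "results"
    schema: dict = field(default_factory=dict)
    volume_rho: float = 0.1
    redundancy_rho: float = 0.7
    redundancy_order: str = "variance_desc"
    tsrc_threshold: float = 33.0
    tsrc_convention: str = "reduction_all"
    aggregators: list[str] = field(default_factory=lambda: list(AGGREGATORS))
    zscore_scope: str = "cohort"
    cv_folds: int = 5
    cv_seed: int = 0
    c_grid: list[float] = field(default_factory=lambda: [10.0 ** k for k in range(-3, 4)])
    km_split: str = "median"
    mirv_metrics_for_models: list[str] = field(
        default_factory=lambda: ["mirv_distance_max", "mirv_dissimilarity_max"]
    )
    recist_order: dict = field(default_factory=lambda: dict(RECIST_ORDER))
    histology_order: dict = field(default_factory=dict)  # empty => sorted levels

    def __post_init__(self) -> None:
        if not 0 <= self.volume_rho <= 1:
            raise ConfigError(f"volume_rho must be in [0, 1], got {self.volume_rho}")
        if not 0 <= self.redundancy_rho <= 1:
            raise ConfigError(f"redundancy_rho must be in [0, 1], got {self.redundancy_rho}")
        if self.tsrc_threshold <= 0:
            raise ConfigError("tsrc_threshold must be positive")
        if self.tsrc_convention not in ("reduction_all", "no_growth_all"):
            raise ConfigError(f"unknown tsrc_convention {self.tsrc_convention!r}")
        if self.zscore_scope not in ("cohort", "per_patient"):
            raise ConfigError(f"unknown zscore_scope {self.zscore_scope!r}")
        if self.km_split not in ("median", "fixed"):
            raise ConfigError(f"unknown km_split {self.km_split!r}")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        bad = [a for a in self.aggregators if a not in AGGREGATORS]
        if bad:
            raise ConfigError(f"unknown aggregator(s) {bad}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _ctdna_binary(series: pd.Series) -> pd.Series:
    return series.map({"positive": 1.0, "negative": 0.0, "missing": np.nan})


def _encode_clinical(clin: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    out = clin.copy()
    hist_map = cfg.histology_order or {
        h: i for i, h in enumerate(sorted(out["histology"].unique()))
    }
    coded = ordinal_encode(out, {"histology": hist_map, "recist": cfg.recist_order})
    out["histology_ord"] = coded["histology"]
    out["recist_ord"] = coded["recist"]
    out["ctdna_pre_bin"] = _ctdna_binary(out["ctdna_pre"])
    out["ctdna_post_bin"] = _ctdna_binary(out["ctdna_post"])
    return out


def _model_suite(
    table: pd.DataFrame, endpoint: str, cfg: RunConfig, notices: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Nested logistic models (baseline / +MIRV / +MIRV+RECIST) for one endpoint."""
    base_covs = ["age_ge_65", "performance_status", "histology_ord", "total_volume"]
    specs = [
        ("baseline", base_covs),
        ("baseline+mirv", base_covs + cfg.mirv_metrics_for_models),
        ("baseline+mirv+recist", base_covs + cfg.mirv_metrics_for_models + ["recist_ord"]),
    ]
    sub = table.dropna(subset=[endpoint] + specs[-1][1])
    y = sub[endpoint].astype(int)
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < cfg.cv_folds:
        notices.append(
            f"model suite for {endpoint} skipped: needs >= {cfg.cv_folds} per class, "
            f"found {counts.to_dict()}"
        )
        return pd.DataFrame(), pd.DataFrame(), pd.DataFrame()
    evals = []
    for label, covs in specs:
        evals.append(
            fit_cv_logistic(
                sub[covs], y, model_label=f"{endpoint}:{label}",
                folds=cfg.cv_folds, seed=cfg.cv_seed, c_grid=tuple(cfg.c_grid),
            )
        )
    model_rows = [
        {
            "model": ev.model_label,
            "mean_auc": ev.mean_auc,
            "sd_auc": ev.sd_auc,
            "fold_aucs": ";".join(f"{a:.6f}" for a in ev.fold_aucs),
            "best_C": ";".join(f"{c:g}" for c in ev.best_C),
            "n": len(sub),
        }
        for ev in evals
    ]
    cmp_rows = []
    for i in range(len(evals)):
        for j in range(i + 1, len(evals)):
            res = compare_auc(evals[j], evals[i])
            cmp_rows.append(
                {
                    "model_a": evals[j].model_label,
                    "model_b": evals[i].model_label,
                    "z": res["z"],
                    "p_value": res["p_value"],
                    "degenerate": res["degenerate"],
                }
            )
    roc_rows = pd.concat(
        [
            pd.DataFrame(
                {"model": ev.model_label, "fpr": ev.mean_fpr, "tpr": ev.mean_tpr}
            )
            for ev in evals
        ],
        ignore_index=True,
    )
    return pd.DataFrame(model_rows), pd.DataFrame(cmp_rows), roc_rows


def run_pipeline(config: RunConfig, seed: int | None = None) -> dict:
    """Execute the full analysis and write result CSVs plus a run log.

    Returns a summary dict with the manifest and per-stage notices.
    """
    t0 = time.time()
    seed = config.cv_seed if seed is None else seed
    schema = TableSchema.from_dict(config.schema) if config.schema else TableSchema()
    notices: list[str] = []
    timings: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}

    def _stage(name):
        timings[name] = time.time()

    # ---- load
    _stage("load")
    matrices = read_feature_table(config.feature_table, schema)
    if BASELINE not in matrices:
        raise StageError("load: feature table has no baseline rows")
    baseline = matrices[BASELINE]
    followup = matrices.get(FOLLOWUP)
    clinical = None
    if config.clinical_table:
        clinical = clinical_frame(read_clinical_table(config.clinical_table, schema))

    # ---- reduce
    _stage("reduce")
    try:
        reduced, report = reduce_features(
            baseline,
            volume_rho=config.volume_rho,
            redundancy_rho=config.redundancy_rho,
            redundancy_order=config.redundancy_order,
        )
    except StageError as exc:
        raise StageError(f"reduce: {exc}") from exc
    tables["reduction_report"] = report.to_frame()

    # ---- mirv
    _stage("mirv")
    zscored = zscore_features(reduced, scope=config.zscore_scope)
    mirv_table, excluded = compute_mirv(zscored, tuple(config.aggregators))
    if excluded:
        notices.append(f"mirv: excluded single-lesion patients: {excluded}")
    tables["mirv"] = mirv_table

    # ---- response
    _stage("response")
    response_patient = None
    if followup is not None:
        lesion_tab, response_patient = compute_response(
            baseline, followup, config.tsrc_threshold, config.tsrc_convention
        )
        tables["response_lesions"] = lesion_tab
        tables["response_patients"] = response_patient
    else:
        notices.append("response: no follow-up rows; stage skipped")

    # ---- association
    _stage("association")
    volmetrics = baseline_volume_metrics(baseline)
    tables["baseline_volume_metrics"] = volmetrics
    patient = mirv_table.merge(volmetrics, on="patient_id")
    if response_patient is not None:
        patient = patient.merge(
            response_patient[["patient_id", "volumetric_response_range", "tsrc"]],
            on="patient_id",
        )
    if clinical is not None:
        enc = _encode_clinical(clinical, config).reset_index()
        patient = patient.merge(enc, on="patient_id", how="left")
    tables["patient_table"] = patient

    mirv_cols = [c for c in patient.columns if c.startswith("mirv_")]
    if response_patient is not None:
        targets = ["volumetric_response_range", "tsrc", "total_volume",
                   "volume_range", "volume_sd"]
        pairs = [(m, t) for m in mirv_cols for t in targets]
        tables["associations_volumetric"] = spearman_matrix(patient, pairs)
    if clinical is not None and patient["ctdna_post_bin"].notna().any():
        targets = ["ctdna_pre_bin", "ctdna_post_bin", "total_volume",
                   "volume_range", "volume_sd"]
        pairs = [(m, t) for m in mirv_cols for t in targets]
        tables["associations_ctdna"] = spearman_matrix(patient, pairs)

    if clinical is not None:
        for endpoint in ["tsrc", "ctdna_post_bin"]:
            if endpoint not in patient.columns:
                continue
            models, comparisons, roc = _model_suite(patient, endpoint, config, notices)
            if len(models):
                tables[f"models_{endpoint}"] = models
                tables[f"model_comparisons_{endpoint}"] = comparisons
                tables[f"roc_{endpoint}"] = roc
    else:
        notices.append("association: no clinical table; model suites skipped")

    # ---- survival
    _stage("survival")
    if clinical is not None:
        covs = ["age_ge_65", "performance_status", "histology_ord", "recist_ord",
                "total_volume"]
        fits = []
        subgroups = []
        for metric in config.mirv_metrics_for_models:
            sub = patient.dropna(subset=["os_years", "os_event"])
            try:
                fit = fit_cox(
                    sub, covariates=covs + [metric],
                    interaction=(metric, "histology_ord"),
                )
                df = fit.to_frame()
                df.insert(0, "model", metric)
                fits.append(df)
            except Exception as exc:
                notices.append(f"survival: Cox for {metric} skipped: {exc}")
            res = km_logrank_subgroups(
                patient.dropna(subset=["os_years", "os_event", metric]),
                "histology", metric, split=config.km_split,
            )
            if res:
                sf = subgroup_frame(res)
                sf.insert(0, "metric", metric)
                subgroups.append(sf)
                km = pd.concat(
                    [r.km_curves.assign(subgroup=r.subgroup, metric=metric) for r in res],
                    ignore_index=True,
                )
                tables[f"km_curves_{metric}"] = km
        if fits:
            tables["cox_coefficients"] = pd.concat(fits, ignore_index=True)
        if subgroups:
            tables["survival_subgroups"] = pd.concat(subgroups, ignore_index=True)
    else:
        notices.append("survival: no clinical table; stage skipped")

    # ---- write
    _stage("write")
    manifest = write_results(tables, config.out_dir)
    elapsed = time.time() - t0
    cfg_dict = asdict(config)
    log_lines = [
        f"mirv version: {__version__}",
        f"config hash: {config_hash(cfg_dict)}",
        f"seed: {seed}",
        f"elapsed_s: {elapsed:.2f}",
    ]
    log_lines += [f"config {k}: {v}" for k, v in sorted(cfg_dict.items())]
    log_lines += [f"notice: {n}" for n in notices]
    log_lines += [f"output {r.file}: {r.n_rows} rows" for r in manifest.itertuples()]
    Path(config.out_dir, "run.log").write_text("\n".join(log_lines) + "\n")
    return {"manifest": manifest, "notices": notices, "tables": tables}
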