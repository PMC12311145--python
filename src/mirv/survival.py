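"""Prognostic evaluation: Cox regression with interactions, KM subgroups.

A multivariable Cox proportional-hazards model (Efron ties) relates
overall survival to a continuous heterogeneity score while controlling for
histology, baseline tumor volume, performance status, age and RECIST
category, optionally with score-by-histology interaction columns. Subgroup
analysis then stratifies each histology level at the within-subgroup median
of the score, compares strata with a two-sample log-rank test, and corrects
the subgroup p-values with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .errors import DataIntegrityError, StageError


@dataclass
class SurvivalFit:
    covariate_names: list[str]
    log_hr: dict[str, float]
    hr_ci_95: dict[str, tuple[float, float]]
    p_value: dict[str, float]
    interaction_terms: list[str] = field(default_factory=list)
    n: int = 0
    n_events: int = 0
    # fitted lifelines model, kept for diagnostics (check_assumptions etc.)
    fitter: CoxPHFitter | None = field(default=None, repr=False, compare=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "covariate": c,
                "log_hr": self.log_hr[c],
                "hr": float(np.exp(self.log_hr[c])),
                "hr_ci_low": self.hr_ci_95[c][0],
                "hr_ci_high": self.hr_ci_95[c][1],
                "p_value": self.p_value[c],
                "is_interaction": c in self.interaction_terms,
            }
            for c in self.covariate_names
        ]
        return pd.DataFrame(rows)


def add_interaction_columns(
    table: pd.DataFrame, metric: str, by: str
) -> tuple[pd.DataFrame, list[str]]:
    """Append metric x level indicator-product columns for a categorical.

    The first level (sorted) is the reference and gets no column.
    """
    levels = sorted(table[by].astype(str).unique())
    out = table.copy()
    names = []
    for level in levels[1:]:
        col = f"{metric}_x_{by}_{level}"
        out[col] = out[metric] * (out[by].astype(str) == level).astype(float)
        names.append(col)
    return out, names


def fit_cox(
    table: pd.DataFrame,
    duration_col: str = "os_years",
    event_col: str = "os_event",
    covariates: list[str] | None = None,
    interaction: tuple[str, str] | None = None,
) -> SurvivalFit:
    """Multivariable Cox PH fit (Efron approximation for ties).

    ``interaction=(metric, categorical)`` adds metric x level indicator
    products. Errors if there are no events or more parameters than events
    (overfit guard), and surfaces non-convergence with diagnostics.
    """
    if covariates is None:
        covariates = [
            c for c in table.columns if c not in (duration_col, event_col, "patient_id")
        ]
    df = table[[duration_col, event_col] + covariates].copy()
    interaction_names: list[str] = []
    if interaction is not None:
        metric, by = interaction
        df, interaction_names = add_interaction_columns(df, metric, by)
    # categoricals entered ordinally must already be numeric
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise DataIntegrityError(
            f"non-numeric covariate(s) {non_numeric}; encode categoricals first"
        )
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise DataIntegrityError("no events: all observations are censored")
    n_params = df.shape[1] - 2
    if n_params >= n_events:
        raise DataIntegrityError(
            f"{n_params} parameters but only {n_events} events; model is overparameterized"
        )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise StageError(f"Cox model did not converge: {exc}") from exc
    summary = cph.summary
    names = list(summary.index)
    return SurvivalFit(
        covariate_names=names,
        log_hr={c: float(summary.loc[c, "coef"]) for c in names},
        hr_ci_95={
            c: (
                float(np.exp(summary.loc[c, "coef lower 95%"])),
                float(np.exp(summary.loc[c, "coef upper 95%"])),
            )
            for c in names
        },
        p_value={c: float(summary.loc[c, "p"]) for c in names},
        interaction_terms=interaction_names,
        n=len(df),
        n_events=n_events,
        fitter=cph,
    )


@dataclass
class SubgroupResult:
    subgroup: str
    n: int
    split_rule: str
    split_value: float
    log_rank_p: float
    fdr: float
    km_curves: pd.DataFrame  # columns: stratum, time, survival, ci_low, ci_high


def _km_curve(durations, events, label: str) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events, label=label)
    surv = kmf.survival_function_[label]
    ci = kmf.confidence_interval_
    return pd.DataFrame(
        {
            "stratum": label,
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
            "ci_low": ci.iloc[:, 0].to_numpy(dtype=float),
            "ci_high": ci.iloc[:, 1].to_numpy(dtype=float),
        }
    )


def km_logrank_subgroups(
    table: pd.DataFrame,
    subgroup_var: str,
    mirv_metric: str,
    duration_col: str = "os_years",
    event_col: str = "os_event",
    split: str = "median",
    split_value: float | None = None,
) -> list[SubgroupResult]:
    """Per-subgroup high/low stratification with log-rank tests and BH FDR.

    ``split`` is ``median`` (within-subgroup median of the metric) or
    ``fixed`` (an explicit ``split_value``). Subgroups where a stratum ends
    up with fewer than 2 members are skipped. FDR is corrected across the
    subgroups actually tested.
    """
    if split not in ("median", "fixed"):
        raise DataIntegrityError(f"unknown split rule {split!r}")
    if split == "fixed" and split_value is None:
        raise DataIntegrityError("fixed split requires split_value")
    results: list[SubgroupResult] = []
    pvals: list[float] = []
    for level, sub in table.groupby(subgroup_var, sort=True):
        cut = float(sub[mirv_metric].median()) if split == "median" else float(split_value)
        high = sub[sub[mirv_metric] > cut]
        low = sub[sub[mirv_metric] <= cut]
        if len(high) < 2 or len(low) < 2:
            continue  # degenerate split; subgroup skipped
        lr = logrank_test(
            high[duration_col], low[duration_col], high[event_col], low[event_col]
        )
        curves = pd.concat(
            [
                _km_curve(high[duration_col], high[event_col], "high"),
                _km_curve(low[duration_col], low[event_col], "low"),
            ],
            ignore_index=True,
        )
        results.append(
            SubgroupResult(
                subgroup=str(level),
                n=len(sub),
                split_rule=split,
                split_value=cut,
                log_rank_p=float(lr.p_value),
                fdr=np.nan,
                km_curves=curves,
            )
        )
        pvals.append(float(lr.p_value))
    if results:
        fdr = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(results, fdr):
            r.fdr = float(q)
    return results


def subgroup_frame(results: list[SubgroupResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subgroup": r.subgroup,
                "n": r.n,
                "split_rule": r.split_rule,
                "split_value": r.split_value,
                "log_rank_p": r.log_rank_p,
                "fdr": r.fdr,
            }
            for r in results
        ]
    )
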