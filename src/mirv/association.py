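"""Association of MIRV with response metrics.

Two analysis styles mirror the evaluation framework around the
heterogeneity score:

* Spearman rank-correlation panels between patient-level variables (MIRV
  aggregates, volumetric response, TSRC, ctDNA labels, baseline volume
  controls), with Benjamini-Hochberg FDR applied once across each panel;
* L2-regularized logistic models evaluated with outer stratified 5-fold
  cross-validation and an inner grid search over the regularization
  strength C in 10^{-3..3}, scored by held-out ROC AUC; nested feature sets
  are compared with a paired per-fold Z-test on the AUC differences.

The Z-test uses only quantities the CV produces (k per-fold AUC
differences) and is approximate for small k; it is the nested-model
comparison reported alongside mean +/- SD AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .errors import DataIntegrityError
from .io import FeatureMatrix

DEFAULT_C_GRID = tuple(10.0 ** k for k in range(-3, 4))
DEFAULT_FPR_GRID = np.linspace(0.0, 1.0, 101)


# ---------------------------------------------------------------------------
# Spearman correlation panels


def spearman_matrix(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Spearman rho with two-sided p and BH FDR for each variable pair.

    ``pairs`` defaults to all unordered column pairs. Missing values are
    handled by pairwise-complete deletion; a pair with a constant variable
    (after deletion) or fewer than 3 complete observations is flagged
    undefined and excluded from the BH family.
    """
    if pairs is None:
        cols = list(table.columns)
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    rows = []
    for a, b in pairs:
        if a not in table.columns or b not in table.columns:
            raise DataIntegrityError(f"unknown variable(s) in pair ({a}, {b})")
        sub = table[[a, b]].dropna()
        n = len(sub)
        if n < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            rows.append({"var_a": a, "var_b": b, "n": n, "rho": np.nan, "p_value": np.nan})
            continue
        res = stats.spearmanr(sub[a], sub[b])
        rows.append(
            {"var_a": a, "var_b": b, "n": n, "rho": float(res.statistic),
             "p_value": float(res.pvalue)}
        )
    out = pd.DataFrame(rows, columns=["var_a", "var_b", "n", "rho", "p_value"])
    out["fdr"] = np.nan
    defined = out["p_value"].notna()
    if defined.any():
        out.loc[defined, "fdr"] = multipletests(
            out.loc[defined, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def baseline_volume_metrics(fm: FeatureMatrix) -> pd.DataFrame:
    """Per-patient baseline volume controls: total, range, sample SD (mm^3).

    SD is reported as 0 for single-lesion patients.
    """
    rows = []
    for pid, sub in fm.volumes.groupby(level=0, sort=True):
        v = sub.to_numpy(dtype=float)
        rows.append(
            {
                "patient_id": str(pid),
                "total_volume": float(v.sum()),
                "volume_range": float(v.max() - v.min()),
                "volume_sd": 0.0 if len(v) < 2 else float(np.std(v, ddof=1)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validated logistic evaluation


@dataclass
class ModelEval:
    model_label: str
    fold_aucs: list[float]
    best_C: list[float]
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    fold_assignments: np.ndarray | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))


def ordinal_encode(table: pd.DataFrame, mappings: dict[str, dict]) -> pd.DataFrame:
    """Encode categorical columns as ordinal integers via explicit mappings."""
    out = table.copy()
    for col, mapping in mappings.items():
        unknown = set(out[col].dropna().unique()) - set(mapping)
        if unknown:
            raise DataIntegrityError(f"column {col}: no ordinal code for {sorted(unknown)}")
        out[col] = out[col].map(mapping)
    return out


def fit_cv_logistic(
    features: pd.DataFrame,
    outcome,
    model_label: str = "model",
    folds: int = 5,
    seed: int = 0,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    inner_folds: int = 3,
    fpr_grid: np.ndarray = DEFAULT_FPR_GRID,
) -> ModelEval:
    """Outer stratified k-fold CV of an L2 logistic model with inner C search.

    Within each training fold, continuous features are standardized on
    training-fold statistics only (scaler inside the pipeline) and C is
    chosen by mean held-out AUC over an inner stratified split. Per-fold
    AUC is computed on the held-out outer fold; the mean ROC curve is the
    average of the per-fold TPRs linearly interpolated onto a common FPR
    grid, pinned at (0,0) and (1,1).
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=int)
    if X.shape[0] != len(y):
        raise DataIntegrityError("features and outcome length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise DataIntegrityError(f"outcome must be binary, found classes {classes.tolist()}")
    if counts.min() < folds:
        raise DataIntegrityError(
            f"minority class has {counts.min()} members; "
            f"stratified {folds}-fold CV needs at least {folds} per class"
        )

    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            # lbfgs with the default ridge penalty == L2-regularized logistic
            ("logit", LogisticRegression(solver="lbfgs", max_iter=1000)),
        ]
    )
    param_grid = {"logit__C": list(c_grid)}

    fold_aucs: list[float] = []
    best_C: list[float] = []
    tprs: list[np.ndarray] = []
    assignments = np.empty(len(y), dtype=int)
    for k, (tr, te) in enumerate(outer.split(X, y)):
        assignments[te] = k
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed + 1)
        search = GridSearchCV(pipe, param_grid, scoring="roc_auc", cv=inner, n_jobs=1)
        search.fit(X[tr], y[tr])
        scores = search.predict_proba(X[te])[:, 1]
        fold_aucs.append(float(roc_auc_score(y[te], scores)))
        best_C.append(float(search.best_params_["logit__C"]))
        fpr, tpr, _ = roc_curve(y[te], scores)
        interp = np.interp(fpr_grid, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    return ModelEval(
        model_label=model_label,
        fold_aucs=fold_aucs,
        best_C=best_C,
        mean_fpr=np.asarray(fpr_grid, dtype=float),
        mean_tpr=mean_tpr,
        feature_names=list(features.columns),
        fold_assignments=assignments,
    )


def compare_auc(model_a: ModelEval, model_b: ModelEval) -> dict:
    """Paired per-fold Z-test on AUC differences between two models.

    z = mean(d) / (sd(d) / sqrt(k)) with a two-sided normal p-value.
    Requires both models to have been evaluated on the same folds. The
    all-zero-difference case returns z = 0, p = 1; a nonzero constant
    difference (sd = 0) is degenerate and reported as p = 0 with a flag.
    """
    if len(model_a.fold_aucs) != len(model_b.fold_aucs):
        raise DataIntegrityError("models were evaluated on different numbers of folds")
    if (
        model_a.fold_assignments is not None
        and model_b.fold_assignments is not None
        and not np.array_equal(model_a.fold_assignments, model_b.fold_assignments)
    ):
        raise DataIntegrityError("models were evaluated on different fold assignments")
    d = np.asarray(model_a.fold_aucs) - np.asarray(model_b.fold_aucs)
    k = len(d)
    sd = float(np.std(d, ddof=1))
    if np.allclose(d, 0.0):
        return {"z": 0.0, "p_value": 1.0, "degenerate": False}
    if sd == 0.0:
        return {"z": float(np.sign(d.mean()) * np.inf), "p_value": 0.0, "degenerate": True}
    z = float(d.mean() / (sd / np.sqrt(k)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {"z": z, "p_value": p, "degenerate": False}
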