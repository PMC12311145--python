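"""Stepwise three-stage radiomic feature reduction.

Stages, applied strictly in order on the pooled baseline lesion table
(all lesions, all patients, raw un-normalized values):

1. low variance — drop features whose sample variance is strictly below the
   median variance of all input features (ties at the median are kept);
2. volume de-correlation — drop features with |Spearman rho| > 0.1 against
   per-lesion voxel volume, so downstream heterogeneity scores are not
   surrogates for tumor size;
3. redundancy — greedy elimination so every kept pair has |Spearman rho| <= 0.7.

The greedy scan orders features by variance descending (name ascending as
tie-break) and drops a feature when it correlates too strongly with any
feature already kept; the field convention of keeping the higher-variance
member of a redundant pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataIntegrityError, StageError
from .io import FeatureMatrix

DEFAULT_VOLUME_RHO = 0.1
DEFAULT_REDUNDANCY_RHO = 0.7


@dataclass
class ReductionReport:
    """Which features each stage removed and why.

    ``kept`` plus all dropped lists is a disjoint partition of the input
    feature set.
    """

    kept: list[str]
    dropped_low_variance: list[str]
    dropped_volume_correlated: list[tuple[str, float]]  # (feature, rho with volume)
    dropped_redundant: list[tuple[str, str, float]]  # (dropped, retained partner, rho)
    thresholds: dict = field(default_factory=dict)

    @property
    def input_features(self) -> set[str]:
        return (
            set(self.kept)
            | set(self.dropped_low_variance)
            | {f for f, _ in self.dropped_volume_correlated}
            | {f for f, _, _ in self.dropped_redundant}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature": f, "status": "kept", "detail": ""} for f in self.kept]
        rows += [
            {"feature": f, "status": "dropped_low_variance", "detail": ""}
            for f in self.dropped_low_variance
        ]
        rows += [
            {"feature": f, "status": "dropped_volume_correlated", "detail": f"rho={r:.4f}"}
            for f, r in self.dropped_volume_correlated
        ]
        rows += [
            {"feature": f, "status": "dropped_redundant", "detail": f"partner={p};rho={r:.4f}"}
            for f, p, r in self.dropped_redundant
        ]
        return pd.DataFrame(rows, columns=["feature", "status", "detail"])


def _sample_variances(fm: FeatureMatrix) -> pd.Series:
    if fm.n_lesions < 2:
        raise DataIntegrityError("variance undefined: need at least 2 lesions")
    return fm.values.var(axis=0, ddof=1)


def filter_low_variance(fm: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Drop features with sample variance strictly below the median variance."""
    variances = _sample_variances(fm)
    median = variances.median()
    dropped = [f for f in fm.feature_names if variances[f] < median]
    kept = [f for f in fm.feature_names if f not in set(dropped)]
    return fm.subset_features(kept), dropped


def _spearman_with(fm: FeatureMatrix, target: np.ndarray) -> pd.Series:
    """|Spearman rho| of each feature against a target vector (average ranks)."""
    if fm.n_lesions < 3:
        raise DataIntegrityError("Spearman correlation needs at least 3 lesions")
    if np.all(target == target[0]):
        raise DataIntegrityError("target vector is constant; ranks are degenerate")
    rho = np.empty(len(fm.feature_names))
    for k, f in enumerate(fm.feature_names):
        col = fm.values[f].to_numpy()
        if np.all(col == col[0]):
            rho[k] = 0.0  # constant feature carries no monotone volume signal
        else:
            rho[k] = stats.spearmanr(col, target).statistic
    return pd.Series(rho, index=fm.feature_names)


def filter_volume_correlated(
    fm: FeatureMatrix,
    volumes: pd.Series | np.ndarray | None = None,
    rho_max: float = DEFAULT_VOLUME_RHO,
) -> tuple[FeatureMatrix, list[tuple[str, float]]]:
    """Drop features with |Spearman rho| > rho_max against lesion voxel volume.

    Correlation is computed across all lesions pooled over patients.
    """
    vol = fm.volumes.to_numpy() if volumes is None else np.asarray(volumes, dtype=float)
    if len(vol) != fm.n_lesions:
        raise DataIntegrityError("volume vector is not aligned to the feature matrix")
    rho = _spearman_with(fm, vol)
    dropped = [(f, float(rho[f])) for f in fm.feature_names if abs(rho[f]) > rho_max]
    kept = [f for f in fm.feature_names if abs(rho[f]) <= rho_max]
    return fm.subset_features(kept), dropped


def filter_redundant(
    fm: FeatureMatrix,
    rho_max: float = DEFAULT_REDUNDANCY_RHO,
    order: str = "variance_desc",
) -> tuple[FeatureMatrix, list[tuple[str, str, float]]]:
    """Greedy redundancy elimination: kept pairs all satisfy |rho| <= rho_max."""
    if order not in ("variance_desc", "name_asc"):
        raise DataIntegrityError(f"unknown redundancy order {order!r}")
    if fm.n_lesions < 3:
        raise DataIntegrityError("Spearman correlation needs at least 3 lesions")
    names = list(fm.feature_names)
    if order == "variance_desc":
        variances = _sample_variances(fm)
        names = sorted(names, key=lambda f: (-variances[f], f))
    else:
        names = sorted(names)

    # rank-transform once; Pearson on average ranks == Spearman
    ranks = fm.values.rank(axis=0, method="average")
    rho_matrix = ranks.corr(method="pearson")

    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for f in names:
        partner = None
        for g in kept:
            r = rho_matrix.loc[f, g]
            if np.isnan(r):
                continue  # constant column: no monotone association
            if abs(r) > rho_max:
                partner = (g, float(r))
                break
        if partner is None:
            kept.append(f)
        else:
            dropped.append((f, partner[0], partner[1]))

    kept_in_input_order = [f for f in fm.feature_names if f in set(kept)]
    return fm.subset_features(kept_in_input_order), dropped


def reduce_features(
    fm: FeatureMatrix,
    volume_rho: float = DEFAULT_VOLUME_RHO,
    redundancy_rho: float = DEFAULT_REDUNDANCY_RHO,
    redundancy_order: str = "variance_desc",
) -> tuple[FeatureMatrix, ReductionReport]:
    """Run the full variance -> volume -> redundancy pipeline.

    Raises StageError naming the stage if any stage empties the feature set.
    """
    stage1, dropped_var = filter_low_variance(fm)
    if not stage1.feature_names:
        raise StageError("no features survive the low-variance stage")
    stage2, dropped_vol = filter_volume_correlated(stage1, rho_max=volume_rho)
    if not stage2.feature_names:
        raise StageError("no features survive the volume-correlation stage")
    stage3, dropped_red = filter_redundant(stage2, rho_max=redundancy_rho, order=redundancy_order)
    if not stage3.feature_names:
        raise StageError("no features survive the redundancy stage")
    report = ReductionReport(
        kept=list(stage3.feature_names),
        dropped_low_variance=dropped_var,
        dropped_volume_correlated=dropped_vol,
        dropped_redundant=dropped_red,
        thresholds={
            "variance_rule": "below median",
            "volume_rho": volume_rho,
            "redundancy_rho": redundancy_rho,
            "redundancy_order": redundancy_order,
        },
    )
    return stage3, report
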