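"""MIRV: per-patient intertumor heterogeneity from pairwise lesion distances.

For each patient with >= 2 baseline lesions, every unordered lesion pair
(i, j), i != j contributes

* a Euclidean distance  d(L_i, L_j) = ||L_i - L_j||_2, and
* a cosine dissimilarity 1 - (L_i . L_j) / (||L_i|| ||L_j||), in [0, 2],

computed on z-scored reduced feature vectors. The per-patient score
aggregates those pairs; the maximum is the primary definition (the most
divergent lesion pair dominates), with mean / median / SD as sensitivity
aggregators. Self-pairs are excluded throughout: they contribute zero and
can never be the maximum, but would bias the mean, median and SD.

z-scoring is cohort-wide by default (pooled over all patients' lesions):
per-patient standardization is degenerate for 2-lesion patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import DataIntegrityError, StageError
from .io import FeatureMatrix

AGGREGATORS = ("max", "mean", "median", "sd")
METRIC_FAMILIES = ("distance", "dissimilarity")


def zscore_features(fm: FeatureMatrix, scope: str = "cohort") -> FeatureMatrix:
    """Standardize each feature to mean 0, sample SD 1 (ddof=1).

    ``scope="cohort"`` pools all lesions; ``scope="per_patient"`` standardizes
    within each patient (requires every patient to have >= 2 lesions and
    per-patient nonconstant features).
    """
    if scope not in ("cohort", "per_patient"):
        raise DataIntegrityError(f"unknown z-score scope {scope!r}")
    if fm.n_lesions < 2:
        raise DataIntegrityError("z-scoring needs at least 2 lesions")

    def _z(df: pd.DataFrame) -> pd.DataFrame:
        sd = df.std(axis=0, ddof=1)
        zero = sd[sd == 0].index.tolist()
        if zero:
            raise DataIntegrityError(f"zero-variance feature(s) cannot be z-scored: {zero}")
        return (df - df.mean(axis=0)) / sd

    if scope == "cohort":
        values = _z(fm.values)
    else:
        values = fm.values.groupby(level=0, group_keys=False).apply(_z)
        values = values.loc[fm.values.index]
    return FeatureMatrix(values, fm.volumes, fm.volume_column)


def pairwise_euclidean(vectors: np.ndarray) -> np.ndarray:
    """All n(n-1)/2 unordered-pair Euclidean distances (condensed form)."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise DataIntegrityError("need a 2-D array with at least 2 lesion vectors")
    return pdist(vectors, metric="euclidean")


def pairwise_cosine_dissimilarity(vectors: np.ndarray) -> np.ndarray:
    """All unordered-pair cosine dissimilarities 1 - cos(x, y), in [0, 2]."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise DataIntegrityError("need a 2-D array with at least 2 lesion vectors")
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        bad = np.where(norms == 0)[0].tolist()
        raise DataIntegrityError(f"zero-norm lesion vector(s) at row(s) {bad}")
    d = pdist(vectors, metric="cosine")
    # scipy can leak tiny negatives / >2 overshoots from rounding
    return np.clip(d, 0.0, 2.0)


def _aggregate(pair_values: np.ndarray, aggregators: tuple[str, ...]) -> dict[str, float]:
    out = {}
    for agg in aggregators:
        if agg == "max":
            out[agg] = float(np.max(pair_values))
        elif agg == "mean":
            out[agg] = float(np.mean(pair_values))
        elif agg == "median":
            out[agg] = float(np.median(pair_values))
        elif agg == "sd":
            out[agg] = 0.0 if len(pair_values) < 2 else float(np.std(pair_values, ddof=1))
        else:
            raise DataIntegrityError(f"unknown aggregator {agg!r}")
    return out


@dataclass
class MIRVResult:
    patient_id: str
    n_lesions: int
    n_pairs: int
    distance_agg: dict[str, float]
    dissimilarity_agg: dict[str, float]


def compute_mirv(
    fm: FeatureMatrix,
    aggregators: tuple[str, ...] = AGGREGATORS,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-patient MIRV table from a reduced, z-scored feature matrix.

    Returns (table, excluded) where ``excluded`` lists patients with fewer
    than 2 lesions (MIRV is defined over tumor pairs). Columns follow
    ``mirv_<family>_<aggregator>``.
    """
    for agg in aggregators:
        if agg not in AGGREGATORS:
            raise DataIntegrityError(f"unknown aggregator {agg!r}")
    rows = []
    excluded: list[str] = []
    for pid, sub in fm.values.groupby(level=0, sort=True):
        X = sub.to_numpy(dtype=float)
        if X.shape[0] < 2:
            excluded.append(str(pid))
            continue
        dist = pairwise_euclidean(X)
        dissim = pairwise_cosine_dissimilarity(X)
        row: dict[str, object] = {
            "patient_id": str(pid),
            "n_lesions": X.shape[0],
            "n_pairs": len(dist),
        }
        for agg, val in _aggregate(dist, aggregators).items():
            row[f"mirv_distance_{agg}"] = val
        for agg, val in _aggregate(dissim, aggregators).items():
            row[f"mirv_dissimilarity_{agg}"] = val
        rows.append(row)
    if not rows:
        raise StageError("no patient has >= 2 lesions; MIRV is undefined for this cohort")
    table = pd.DataFrame(rows)
    return table, excluded
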