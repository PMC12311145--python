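"""Lesion- and patient-level treatment-response metrics.

Relative volume change per lesion between baseline and first follow-up,
the per-patient volumetric-response range (max - min of lesion volume
changes, in percent), and the binary tumor-specific response classification
(TSRC): Complete Tumor Response when every lesion meets the volume-change
criterion at the 33% threshold, else Non-/Partial Tumor Response.

The threshold direction is exposed as an explicit convention because the
clinical definition is genuinely ambiguous between "every lesion shrank by
more than 33%" and "no lesion changed by more than 33%":

* ``reduction_all`` (default): TSRC = 1 iff every lesion's dV <= -threshold;
* ``no_growth_all``: TSRC = 1 iff every lesion's dV <= +threshold.

The boundary is inclusive on the response side in both conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataIntegrityError
from .io import FeatureMatrix

DEFAULT_TSRC_THRESHOLD = 33.0
TSRC_CONVENTIONS = ("reduction_all", "no_growth_all")


def volume_change(v_baseline: float, v_followup: float) -> float:
    """Relative volume change in percent: 100 * (V_f - V_b) / V_b."""
    if v_baseline <= 0:
        raise DataIntegrityError(f"baseline volume must be positive, got {v_baseline}")
    if v_followup < 0:
        raise DataIntegrityError(f"follow-up volume must be nonnegative, got {v_followup}")
    return 100.0 * (v_followup - v_baseline) / v_baseline


def volumetric_response_range(deltas) -> float:
    """Range (max - min) of per-lesion volume changes; 0 for a single lesion."""
    deltas = np.asarray(list(deltas), dtype=float)
    if deltas.size == 0:
        raise DataIntegrityError("volumetric response range needs at least one lesion")
    return float(np.max(deltas) - np.min(deltas))


def classify_tsrc(
    deltas,
    threshold_pct: float = DEFAULT_TSRC_THRESHOLD,
    convention: str = "reduction_all",
) -> int:
    """Binary TSRC: 1 = Complete Tumor Response, 0 = Non-/Partial."""
    if convention not in TSRC_CONVENTIONS:
        raise DataIntegrityError(f"unknown TSRC convention {convention!r}")
    deltas = np.asarray(list(deltas), dtype=float)
    if deltas.size == 0:
        raise DataIntegrityError("TSRC needs at least one lesion")
    bound = -threshold_pct if convention == "reduction_all" else threshold_pct
    return int(np.all(deltas <= bound))


@dataclass
class ResponseRecord:
    patient_id: str
    lesion_deltas: dict[str, float]
    volumetric_response_range: float
    tsrc: int
    threshold_pct: float = DEFAULT_TSRC_THRESHOLD
    convention: str = "reduction_all"


def compute_response(
    baseline: FeatureMatrix,
    followup: FeatureMatrix,
    threshold_pct: float = DEFAULT_TSRC_THRESHOLD,
    convention: str = "reduction_all",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lesion volume changes and per-patient response summary.

    Lesions are matched across timepoints by (patient_id, lesion_id); a
    patient is scored only when every baseline lesion has a matched
    follow-up volume, otherwise an error lists the unmatched lesions.

    Returns (lesion_table, patient_table).
    """
    vb = baseline.volumes
    vf = followup.volumes
    unmatched = vb.index.difference(vf.index)
    if len(unmatched):
        raise DataIntegrityError(
            f"baseline lesions without matched follow-up: {list(unmatched)}"
        )
    lesion_rows = []
    patient_rows = []
    for pid, sub in vb.groupby(level=0, sort=True):
        deltas = {}
        for (p, lid), v0 in sub.items():
            dv = volume_change(float(v0), float(vf.loc[(p, lid)]))
            deltas[lid] = dv
            lesion_rows.append(
                {
                    "patient_id": str(pid),
                    "lesion_id": str(lid),
                    "volume_baseline": float(v0),
                    "volume_followup": float(vf.loc[(p, lid)]),
                    "delta_volume_pct": dv,
                }
            )
        patient_rows.append(
            {
                "patient_id": str(pid),
                "n_lesions": len(deltas),
                "volumetric_response_range": volumetric_response_range(deltas.values()),
                "tsrc": classify_tsrc(deltas.values(), threshold_pct, convention),
                "threshold_pct": threshold_pct,
                "convention": convention,
            }
        )
    return pd.DataFrame(lesion_rows), pd.DataFrame(patient_rows)
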