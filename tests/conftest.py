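import numpy as np
import pandas as pd
import pytest

from mirv.io import FeatureMatrix


def make_fm(values, feature_names=None, volumes=None, patients=None):
    """Build a FeatureMatrix from a plain array for tests.

    ``patients`` maps each row to a patient id; default puts every lesion
    under one patient.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    feature_names = feature_names or [f"f{k}" for k in range(values.shape[1])]
    patients = patients or ["P1"] * n
    lesion_ids = []
    seen: dict[str, int] = {}
    for p in patients:
        seen[p] = seen.get(p, 0) + 1
        lesion_ids.append(f"L{seen[p]}")
    idx = pd.MultiIndex.from_arrays([patients, lesion_ids], names=["patient_id", "lesion_id"])
    vols = np.full(n, 100.0) if volumes is None else np.asarray(volumes, dtype=float)
    return FeatureMatrix(
        pd.DataFrame(values, index=idx, columns=feature_names),
        pd.Series(vols, index=idx, name="voxel_volume"),
    )


def spearman_no_ties(a, b):
    """Independent closed-form Spearman for distinct values: 1 - 6*sum(d^2)/(n(n^2-1))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ra = a.argsort().argsort() + 1
    rb = b.argsort().argsort() + 1
    n = len(a)
    return 1.0 - 6.0 * float(np.sum((ra - rb) ** 2)) / (n * (n ** 2 - 1))


def bh_stepup(pvals):
    """Independent Benjamini-Hochberg step-up oracle."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        k = m - rank_from_top  # 1-based rank of this p-value
        running = min(running, p[i] * m / k)
        adj[i] = running
    return adj


@pytest.fixture(scope="session")
def small_cohort():
    from mirv.synthetic import SyntheticConfig, generate_cohort

    return generate_cohort(SyntheticConfig(n_patients=40, seed=123))
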