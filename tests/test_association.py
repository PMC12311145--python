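"""Correlation panels, CV logistic evaluation and paired AUC comparison."""

import numpy as np
import pandas as pd
import pytest

from mirv.association import (
    baseline_volume_metrics,
    compare_auc,
    fit_cv_logistic,
    ordinal_encode,
    spearman_matrix,
)
from mirv.errors import DataIntegrityError

from conftest import bh_stepup, make_fm


class TestSpearmanMatrix:
    def test_perfect_monotone(self):
        t = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 4, 6, 8], "z": [8, 6, 4, 2]})
        res = spearman_matrix(t).set_index(["var_a", "var_b"])
        assert res.loc[("x", "y"), "rho"] == pytest.approx(1.0)
        assert res.loc[("x", "z"), "rho"] == pytest.approx(-1.0)

    def test_fdr_matches_stepup_oracle(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
        res = spearman_matrix(t)
        np.testing.assert_allclose(res["fdr"], bh_stepup(res["p_value"]), atol=1e-12)
        assert (res["fdr"] >= res["p_value"] - 1e-12).all()
        assert (res["fdr"] <= 1.0).all()

    def test_constant_variable_excluded_from_family(self):
        t = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3], "flat": [5, 5, 5, 5]})
        res = spearman_matrix(t)
        flat = res[(res["var_a"] == "flat") | (res["var_b"] == "flat")]
        assert flat["rho"].isna().all() and flat["fdr"].isna().all()
        rest = res.dropna(subset=["p_value"])
        np.testing.assert_allclose(rest["fdr"], bh_stepup(rest["p_value"]), atol=1e-12)

    def test_pairwise_complete_deletion(self):
        t = pd.DataFrame(
            {"x": [1, 2, 3, 4, np.nan], "y": [2, 4, 6, 8, 10], "w": [1, 1, 2, 2, 3]}
        )
        res = spearman_matrix(t, [("x", "y"), ("y", "w")]).set_index(["var_a", "var_b"])
        assert res.loc[("x", "y"), "n"] == 4
        assert res.loc[("y", "w"), "n"] == 5


class TestBaselineVolumeMetrics:
    def test_hand_computed(self):
        fm = make_fm([[0.0], [0.0]], volumes=[10, 30], patients=["P1", "P1"])
        row = baseline_volume_metrics(fm).iloc[0]
        assert row["total_volume"] == pytest.approx(40.0)
        assert row["volume_range"] == pytest.approx(20.0)
        assert row["volume_sd"] == pytest.approx(np.sqrt(200.0))

    def test_degenerate_patients(self):
        fm = make_fm(
            [[0.0]] * 4, volumes=[25, 5, 5, 5], patients=["P1", "P2", "P2", "P2"]
        )
        res = baseline_volume_metrics(fm).set_index("patient_id")
        assert res.loc["P1", "total_volume"] == 25.0
        assert res.loc["P1", "volume_range"] == 0.0
        assert res.loc["P1", "volume_sd"] == 0.0
        assert res.loc["P2", "volume_range"] == 0.0
        assert res.loc["P2", "volume_sd"] == 0.0


class TestOrdinalEncode:
    def test_mapping_and_unknown(self):
        t = pd.DataFrame({"recist": ["PR", "SD", "PD"]})
        out = ordinal_encode(t, {"recist": {"CR": 0, "PR": 1, "SD": 2, "PD": 3}})
        assert out["recist"].tolist() == [1, 2, 3]
        with pytest.raises(DataIntegrityError, match="XX"):
            ordinal_encode(pd.DataFrame({"recist": ["XX"]}), {"recist": {"PR": 1}})


def _separable(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    y = (x[:, 0] > 0).astype(int)
    return pd.DataFrame(x, columns=["a", "b", "c"]), y


class TestCvLogistic:
    def test_near_separable_high_auc(self):
        X, y = _separable()
        ev = fit_cv_logistic(X, y, seed=0)
        assert len(ev.fold_aucs) == 5
        assert ev.mean_auc >= 0.95
        assert ev.mean_auc == pytest.approx(np.mean(ev.fold_aucs))
        assert ev.sd_auc == pytest.approx(np.std(ev.fold_aucs, ddof=1))
        assert all(c in (10.0 ** k for k in range(-3, 4)) for c in ev.best_C)

    def test_seed_reproducibility(self):
        X, y = _separable(seed=3)
        a = fit_cv_logistic(X, y, seed=11)
        b = fit_cv_logistic(X, y, seed=11)
        assert a.fold_aucs == b.fold_aucs
        assert np.array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.mean_tpr, b.mean_tpr)

    def test_duplicated_feature_auc_stable(self):
        X, y = _separable(seed=5)
        X2 = X.copy()
        X2["a_dup"] = X2["a"]
        a = fit_cv_logistic(X, y, seed=1)
        b = fit_cv_logistic(X2, y, seed=1)
        assert abs(a.mean_auc - b.mean_auc) <= 0.01

    def test_roc_curve_contract(self):
        X, y = _separable(seed=6)
        ev = fit_cv_logistic(X, y, seed=2)
        assert ev.mean_tpr[0] == 0.0 and ev.mean_tpr[-1] == 1.0
        assert (np.diff(ev.mean_tpr) >= -1e-12).all()
        assert ev.mean_fpr[0] == 0.0 and ev.mean_fpr[-1] == 1.0

    def test_small_minority_class_errors(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(DataIntegrityError, match="minority"):
            fit_cv_logistic(X, y, folds=5)

    def test_non_binary_outcome_errors(self):
        X = pd.DataFrame({"a": np.arange(9.0)})
        with pytest.raises(DataIntegrityError, match="binary"):
            fit_cv_logistic(X, np.arange(9) % 3)


class TestCompareAuc:
    def _ev(self, aucs, assignments=None):
        from mirv.association import ModelEval

        return ModelEval(
            model_label="m", fold_aucs=list(aucs), best_C=[1.0] * len(aucs),
            mean_fpr=np.linspace(0, 1, 3), mean_tpr=np.linspace(0, 1, 3),
            fold_assignments=assignments,
        )

    def test_identical_folds_null(self):
        res = compare_auc(self._ev([0.7, 0.8, 0.75]), self._ev([0.7, 0.8, 0.75]))
        assert res["z"] == 0.0 and res["p_value"] == 1.0

    def test_constant_difference_degenerate(self):
        res = compare_auc(self._ev([0.8, 0.8, 0.8]), self._ev([0.7, 0.7, 0.7]))
        assert res["degenerate"] and res["p_value"] == 0.0

    def test_mismatched_folds_error(self):
        with pytest.raises(DataIntegrityError):
            compare_auc(self._ev([0.7, 0.8]), self._ev([0.7, 0.8, 0.9]))
        with pytest.raises(DataIntegrityError):
            compare_auc(
                self._ev([0.7, 0.8], np.array([0, 1])),
                self._ev([0.7, 0.8], np.array([1, 0])),
            )

    def test_hand_computed_z(self):
        a, b = [0.80, 0.85, 0.78, 0.82, 0.81], [0.75, 0.80, 0.77, 0.79, 0.74]
        d = np.array(a) - np.array(b)
        z_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        res = compare_auc(self._ev(a), self._ev(b))
        assert res["z"] == pytest.approx(z_hand)

    def test_type_one_error_calibration(self):
        """Normal-reference Z on k=5 paired differences is anticonservative.

        The statistic is really t with 4 df, so the true size at nominal
        0.05 is ~0.12; the Monte-Carlo estimate must sit in that band and
        never balloon beyond it.
        """
        from scipy import stats as sps

        rng = np.random.default_rng(9)
        reject = 0
        n_rep = 500
        for _ in range(n_rep):
            d = rng.normal(0, 0.05, size=5)
            res = compare_auc(self._ev(0.7 + d), self._ev([0.7] * 5))
            reject += res["p_value"] < 0.05
        expected = 2 * sps.t.sf(sps.norm.ppf(0.975), df=4)  # ~0.122
        assert abs(reject / n_rep - expected) <= 0.04
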