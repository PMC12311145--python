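"""Three-stage feature reduction: variance, volume de-correlation, redundancy."""

import numpy as np
import pytest

from mirv.errors import DataIntegrityError, StageError
from mirv.reduction import (
    filter_low_variance,
    filter_redundant,
    filter_volume_correlated,
    reduce_features,
)

from conftest import make_fm, spearman_no_ties

# frozen rank constructions (closed-form Spearman, no ties):
# NEAR_ZERO_PERM vs 1..10 has rho = 1 - 6*166/990 = -1/165 ~ -0.006
NEAR_ZERO_PERM = [9, 5, 2, 3, 10, 6, 1, 7, 4, 8]
# chain: rho(a,b)=0.770, rho(b,c)=0.709, rho(a,c)=0.661
CHAIN_B = [1, 2, 4, 9, 5, 3, 6, 7, 8, 10]
CHAIN_C = [3, 1, 6, 5, 7, 2, 9, 4, 8, 10]
RANKS10 = list(range(1, 11))


class TestLowVariance:
    def test_strictly_below_median_dropped(self):
        # variances: const 0, [1..4] 5/3 (the median), doubled 20/3
        fm = make_fm(
            np.column_stack([[7, 7, 7, 7], [1, 2, 3, 4], [2, 4, 6, 8]]),
            feature_names=["const", "mid", "wide"],
        )
        kept, dropped = filter_low_variance(fm)
        assert dropped == ["const"]
        assert kept.feature_names == ["mid", "wide"]  # tie at the median is kept

    def test_equal_variances_nothing_dropped(self):
        fm = make_fm(np.column_stack([[1, 2], [3, 4], [0, 1]]).T)
        _, dropped = filter_low_variance(fm)
        assert dropped == []

    def test_constant_feature_always_dropped(self):
        fm = make_fm(np.column_stack([[5, 5, 5, 5], [1, 2, 3, 4], [1, 3, 5, 7]]))
        _, dropped = filter_low_variance(fm)
        assert "f0" in dropped

    def test_single_row_errors(self):
        with pytest.raises(DataIntegrityError):
            filter_low_variance(make_fm([[1.0, 2.0]]))


class TestVolumeCorrelated:
    def test_feature_equal_to_volume_dropped(self):
        vols = np.arange(10, 110, 10, dtype=float)
        fm = make_fm(np.column_stack([vols, NEAR_ZERO_PERM]), ["isvol", "indep"], vols)
        kept, dropped = filter_volume_correlated(fm)
        assert [f for f, _ in dropped] == ["isvol"]
        assert dropped[0][1] == pytest.approx(1.0)
        assert kept.feature_names == ["indep"]

    def test_near_zero_rho_kept_matches_hand_formula(self):
        vols = np.arange(10, 110, 10, dtype=float)
        assert spearman_no_ties(NEAR_ZERO_PERM, vols) == pytest.approx(-1 / 165)
        fm = make_fm(np.column_stack([NEAR_ZERO_PERM]), ["indep"], vols)
        kept, dropped = filter_volume_correlated(fm)
        assert dropped == [] and kept.feature_names == ["indep"]

    def test_anticorrelated_dropped_by_absolute_value(self):
        vols = np.arange(10, 110, 10, dtype=float)
        fm = make_fm(np.column_stack([-vols]), ["negvol"], vols)
        _, dropped = filter_volume_correlated(fm)
        assert dropped[0][0] == "negvol"
        assert dropped[0][1] == pytest.approx(-1.0)

    def test_constant_volume_errors(self):
        fm = make_fm(np.column_stack([[1, 2, 3]]), volumes=[5, 5, 5])
        with pytest.raises(DataIntegrityError, match="constant"):
            filter_volume_correlated(fm)


class TestRedundant:
    def test_duplicate_features_collapse_to_one(self):
        x = np.array(RANKS10, dtype=float)
        fm = make_fm(np.column_stack([x, x]), ["a", "b"])
        kept, dropped = filter_redundant(fm)
        assert kept.feature_names == ["a"]  # equal variance: name order tie-break
        assert dropped == [("b", "a", pytest.approx(1.0))]

    def test_chain_greedy_keeps_endpoints(self):
        # hand-checked ranks: |rho| above 0.7 for a-b and b-c, below for a-c
        assert spearman_no_ties(RANKS10, CHAIN_B) > 0.7
        assert spearman_no_ties(CHAIN_B, CHAIN_C) > 0.7
        assert abs(spearman_no_ties(RANKS10, CHAIN_C)) <= 0.7
        # scale to order variances a > b > c without changing ranks
        fm = make_fm(
            np.column_stack(
                [3.0 * np.array(RANKS10), 2.0 * np.array(CHAIN_B), 1.0 * np.array(CHAIN_C)]
            ),
            ["a", "b", "c"],
        )
        kept, dropped = filter_redundant(fm)
        assert kept.feature_names == ["a", "c"]
        assert [(d, p) for d, p, _ in dropped] == [("b", "a")]

    def test_independent_features_all_kept(self):
        fm = make_fm(
            np.column_stack([RANKS10, NEAR_ZERO_PERM, CHAIN_C]), ["a", "b", "c"]
        )
        if all(
            abs(spearman_no_ties(x, y)) <= 0.7
            for x, y in [(RANKS10, NEAR_ZERO_PERM), (NEAR_ZERO_PERM, CHAIN_C),
                         (RANKS10, CHAIN_C)]
        ):
            kept, dropped = filter_redundant(fm)
            assert dropped == []
            assert set(kept.feature_names) == {"a", "b", "c"}


class TestReducePipeline:
    # second frozen permutation: rho vs 1..10 = 0.0788, rho vs NEAR_ZERO_PERM = 0.261
    INDEP_PERM = [10, 7, 1, 3, 2, 5, 8, 6, 4, 9]

    def _staged_toy(self):
        """Engineered 10-lesion toy: one named drop per stage.

        All non-degenerate columns are standardized to equal variance so
        the variance stage removes only the near-constant column; keeper
        and indep are rank permutations uncorrelated with volume; volfeat
        tracks volume exactly; dup copies keeper.
        """
        rng = np.random.default_rng(42)
        vols = np.arange(10, 110, 10, dtype=float)

        def unitize(x):
            x = np.asarray(x, dtype=float)
            return 2.0 * (x - x.mean()) / x.std(ddof=1)

        keeper = unitize(NEAR_ZERO_PERM)
        indep = unitize(self.INDEP_PERM)
        volfeat = unitize(vols)
        dup = keeper.copy()
        lowvar = 0.001 * rng.normal(size=10)
        return make_fm(
            np.column_stack([keeper, indep, lowvar, volfeat, dup]),
            ["keeper", "indep", "lowvar", "volfeat", "dup"],
            vols,
        )

    def test_each_stage_drops_named_feature(self):
        fm = self._staged_toy()
        reduced, report = reduce_features(fm)
        assert report.dropped_low_variance == ["lowvar"]
        assert [f for f, _ in report.dropped_volume_correlated] == ["volfeat"]
        # keeper and dup are identical columns; the name-ascending tie-break
        # keeps "dup" and records "keeper" as its redundant partner
        assert [(d, p) for d, p, _ in report.dropped_redundant] == [("keeper", "dup")]
        assert set(report.kept) == {"dup", "indep"}
        assert reduced.feature_names == report.kept

    def test_partition_invariant(self):
        fm = self._staged_toy()
        _, report = reduce_features(fm)
        assert report.input_features == set(fm.feature_names)
        all_dropped = (
            set(report.dropped_low_variance)
            | {f for f, _ in report.dropped_volume_correlated}
            | {f for f, _, _ in report.dropped_redundant}
        )
        assert not (set(report.kept) & all_dropped)

    def test_disabled_thresholds_only_variance_can_drop(self):
        fm = self._staged_toy()
        _, report = reduce_features(fm, volume_rho=1.0, redundancy_rho=1.0)
        assert report.dropped_volume_correlated == []
        assert report.dropped_redundant == []

    def test_column_permutation_same_kept_set(self):
        fm = self._staged_toy()
        _, r1 = reduce_features(fm)
        perm = ["lowvar", "keeper", "volfeat", "indep", "dup"]
        _, r2 = reduce_features(fm.subset_features(perm))
        assert set(r1.kept) == set(r2.kept)

    def test_no_survivor_error_names_stage(self):
        vols = np.arange(10, 110, 10, dtype=float)
        fm = make_fm(np.column_stack([vols, vols * 2.0]), ["v1", "v2"], vols)
        with pytest.raises(StageError, match="volume"):
            reduce_features(fm)

    @pytest.mark.parametrize("seed", range(10))
    def test_postcondition_audit_random_matrices(self, seed):
        """Recomputed checks: kept features pass both correlation thresholds."""
        rng = np.random.default_rng(seed)
        n, f = 30, 12
        vols = rng.lognormal(8, 0.7, n)
        X = rng.normal(size=(n, f))
        X[:, 0] += 0.5 * np.log(vols)  # plant a volume confounder
        X[:, 1] = X[:, 2] * 0.95 + 0.05 * rng.normal(size=n)  # plant redundancy
        fm = make_fm(X, volumes=vols)
        reduced, report = reduce_features(fm)
        assert report.input_features == set(fm.feature_names)
        from scipy import stats

        for f1 in reduced.feature_names:
            rho = stats.spearmanr(reduced.values[f1], vols).statistic
            assert abs(rho) <= 0.1 + 1e-12
            for f2 in reduced.feature_names:
                if f1 < f2:
                    r = stats.spearmanr(reduced.values[f1], reduced.values[f2]).statistic
                    assert abs(r) <= 0.7 + 1e-12

    def test_determinism(self):
        fm = self._staged_toy()
        a = reduce_features(fm)
        b = reduce_features(fm.copy())
        assert a[1] == b[1]
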