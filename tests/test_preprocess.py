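"""Normalization and feature-retention behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omixplain.preprocess import (
    aggregate_features,
    filter_metabolite_peaks,
    filter_prevalent_features,
    to_cpm,
    to_relative_abundance,
    zscore_standardize,
)
from omixplain.tables import TableValidationError

from conftest import make_feature_table


class TestClosure:
    def test_relative_abundance_of_a_row(self):
        t = to_relative_abundance(make_feature_table([[2.0, 3.0, 5.0]]))
        assert t.values.tolist() == [[0.2, 0.3, 0.5]]
        assert t.value_kind == "relative"

    def test_single_feature_closes_to_one(self):
        t = to_relative_abundance(make_feature_table([[7.0]]))
        assert t.values.tolist() == [[1.0]]

    def test_zero_row_sum_is_an_error(self):
        with pytest.raises(TableValidationError, match="zero total"):
            to_relative_abundance(make_feature_table([[0.0, 0.0]]))
        with pytest.raises(TableValidationError, match="zero total"):
            to_cpm(make_feature_table([[0.0, 0.0]]))

    def test_cpm_of_a_row(self):
        t = to_cpm(make_feature_table([[2.0, 3.0, 5.0]]))
        assert t.values.tolist() == [[200000.0, 300000.0, 500000.0]]
        t2 = to_cpm(make_feature_table([[1.0, 0.0]]))
        assert t2.values.tolist() == [[1e6, 0.0]]

    def test_closure_commutes_with_sample_permutation(self):
        rng = np.random.default_rng(0)
        t = make_feature_table(rng.uniform(0.1, 5.0, (5, 4)))
        perm = [3, 0, 4, 1, 2]
        ids = [t.sample_ids[i] for i in perm]
        a = to_relative_abundance(t).reorder_samples(ids)
        b = to_relative_abundance(t.reorder_samples(ids))
        pd.testing.assert_frame_equal(a.data, b.data)


class TestAggregateFeatures:
    def test_sums_mapped_features_and_drops_the_rest(self):
        t = to_cpm(make_feature_table([[1.0, 2.0, 3.0, 4.0]]))
        out = aggregate_features(t, {"f1": "M1", "f2": "M1", "f3": "M2"})
        # partial mapping: the closed cpm kind is downgraded to counts
        assert out.value_kind == "count"
        np.testing.assert_allclose(out.data["M1"], [3e5], atol=1e-9)
        np.testing.assert_allclose(out.data["M2"], [3e5], atol=1e-9)

    def test_partition_preserves_closed_kind(self):
        t = to_cpm(make_feature_table([[1.0, 2.0, 3.0, 4.0]]))
        out = aggregate_features(t, {"f1": "M1", "f2": "M1", "f3": "M2", "f4": "M2"})
        assert out.value_kind == "cpm"
        np.testing.assert_allclose(out.values.sum(axis=1), 1e6, atol=1e-3)

    def test_empty_mapping_rejected(self):
        t = make_feature_table([[1.0, 2.0]])
        with pytest.raises(ValueError, match="no feature"):
            aggregate_features(t, {"zzz": "M1"})


class TestPrevalenceFilter:
    GROUPS = pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})

    def test_uniformly_abundant_feature_retained(self):
        t = make_feature_table(np.full((4, 1), 0.002), value_kind="count")
        out = filter_prevalent_features(t, self.GROUPS, 0.001, 0.5)
        assert out.feature_ids == ["f1"]

    def test_feature_failing_one_group_removed(self):
        # passes in all of A but 0/2 of B -> the every-group rule removes it
        vals = np.array(
            [[0.5, 0.5],
             [0.5, 0.5],
             [0.0005, 0.9995],
             [0.0005, 0.9995]]
        )
        t = make_feature_table(vals, value_kind="relative")
        out = filter_prevalent_features(t, self.GROUPS, 0.001, 0.5)
        assert out.feature_ids == ["f2"]

    def test_zero_threshold_keeps_everything_positive(self):
        rng = np.random.default_rng(1)
        t = make_feature_table(rng.uniform(0.1, 1.0, (4, 6)))
        out = filter_prevalent_features(t, self.GROUPS, 0.0, 0.5)
        assert out.feature_ids == t.feature_ids

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        raw = make_feature_table(rng.lognormal(0, 2, (4, 30)))
        t = to_relative_abundance(raw)
        once = filter_prevalent_features(t, self.GROUPS, 0.01, 0.5)
        twice = filter_prevalent_features(once, self.GROUPS, 0.01, 0.5)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_relative_table_reclosed_after_filter(self):
        rng = np.random.default_rng(3)
        t = to_relative_abundance(make_feature_table(rng.lognormal(0, 2, (4, 20))))
        out = filter_prevalent_features(t, self.GROUPS, 0.02, 0.5)
        assert out.n_features < 20
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-9)

    def test_bad_min_fraction_and_missing_group(self):
        t = make_feature_table(np.ones((4, 2)))
        with pytest.raises(ValueError, match="min_fraction"):
            filter_prevalent_features(t, self.GROUPS, 0.1, 0.0)
        with pytest.raises(ValueError, match="without group"):
            filter_prevalent_features(t, self.GROUPS.drop("s4"), 0.1, 0.5)


class TestMetabolitePeakFilter:
    @staticmethod
    def _table(values, similarity, identified):
        n_feat = np.asarray(values).shape[1]
        meta = pd.DataFrame(
            {"similarity": similarity, "identified": identified},
            index=[f"f{j + 1}" for j in range(n_feat)],
        )
        return make_feature_table(
            values, layer_kind="rumen_metabolome", value_kind="intensity", meta=meta
        )

    def test_hand_fixture_survivors(self):
        # m1 clean; m2 RSD = (sqrt(2)/2)*100 ~ 70.7% > 30; m3 similarity 150;
        # m4 unidentified; m5 present in 1/4; m6 RSD ~ 8.2% retained
        vals = np.array(
            [
                [10.0, 1.0, 10.0, 10.0, 10.0, 100.0],
                [10.0, 3.0, 11.0, 11.0, np.nan, 90.0],
                [10.0, np.nan, 9.0, 9.0, np.nan, 110.0],
                [10.0, np.nan, 10.0, 10.0, np.nan, 100.0],
            ]
        )
        t = self._table(
            vals,
            similarity=[500, 500, 150, 500, 500, 300],
            identified=[True, True, True, False, True, True],
        )
        out = filter_metabolite_peaks(t)
        assert out.feature_ids == ["f1", "f6"]

    def test_rsd_of_two_point_feature(self):
        # sd(1,3)=sqrt(2), mean 2 -> RSD 70.7% > 30 -> removed
        t = self._table([[1.0, 5.0], [3.0, 5.0], [2.0, 5.0], [2.0, 5.0]],
                        [500, 500], [True, True])
        t.data.iloc[2:, 0] = np.nan
        out = filter_metabolite_peaks(t)
        assert out.feature_ids == ["f2"]

    def test_zero_mean_fails_rsd_with_warning(self):
        t = self._table([[0.0, 1.0]] * 4, [500, 500], [True, True])
        with pytest.warns(UserWarning, match="RSD"):
            out = filter_metabolite_peaks(t)
        assert out.feature_ids == ["f2"]

    def test_qc_samples_restrict_rsd_computation(self):
        vals = np.array([[10.0], [10.0], [1.0], [100.0]])
        t = self._table(vals, [500], [True])
        assert filter_metabolite_peaks(t).n_features == 0
        assert filter_metabolite_peaks(t, qc_samples=["s1", "s2"]).n_features == 1

    def test_meta_required(self):
        t = make_feature_table([[1.0]], layer_kind="rumen_metabolome",
                               value_kind="intensity")
        with pytest.raises(TableValidationError, match="feature_meta"):
            filter_metabolite_peaks(t)


class TestZScore:
    def test_simple_column(self):
        z = zscore_standardize(make_feature_table([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.values.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        t = make_feature_table([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_standardize(t)
        assert z.feature_ids == ["f2"]

    def test_nan_imputed_to_column_mean(self):
        t = make_feature_table([[1.0], [np.nan], [3.0]],
                               layer_kind="rumen_metabolome", value_kind="intensity")
        z = zscore_standardize(t)
        np.testing.assert_allclose(z.values.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            zscore_standardize(make_feature_table([[1.0, 2.0]]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_satisfies_zscore_invariants(self, seed):
        rng = np.random.default_rng(seed)
        t = make_feature_table(rng.lognormal(0, 1, (6, 4)))
        z = zscore_standardize(t)
        assert z.value_kind == "zscore"
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1.0, atol=1e-9)
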