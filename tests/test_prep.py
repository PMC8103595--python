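"""Aggregation and equal-mass binning against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dosebin as db
from dosebin.errors import AggregationError, BinningError
from dosebin.prep import BinDefinition


def brute_force_weighted_quantile(values, weights, p):
    """Sorted cumulative-mass scan: smallest value whose CDF exceeds p."""
    order = np.argsort(values)
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    total = w.sum()
    cum = 0.0
    for i in range(len(v)):
        cum += w[i]
        # accumulate ties before evaluating the CDF at this value
        if i + 1 < len(v) and v[i + 1] == v[i]:
            continue
        if cum / total > p:
            return v[i]
    return v[-1]


class TestWeightedQuantile:
    def test_equal_weight_median_split(self):
        # four equal-mass points: the K=2 cut must split them {1,2} | {3,4}
        cut = db.weighted_quantile([1, 2, 3, 4], [1, 1, 1, 1], [0.5])[0]
        assert cut == 3.0
        d = BinDefinition("x", 2, np.array([cut]))
        np.testing.assert_array_equal(d.assign([1, 2, 3, 4]), [1, 1, 2, 2])

    @given(
        st.lists(st.integers(min_value=-50, max_value=50), min_size=2, max_size=30),
        st.data(),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_matches_brute_force_scan(self, values, data):
        weights = data.draw(
            st.lists(
                st.floats(min_value=0.1, max_value=10.0),
                min_size=len(values),
                max_size=len(values),
            )
        )
        probs = data.draw(
            st.lists(st.floats(min_value=0.01, max_value=0.99), min_size=1, max_size=5)
        )
        got = db.weighted_quantile(np.array(values, float), np.array(weights), probs)
        expected = [brute_force_weighted_quantile(values, weights, p) for p in probs]
        np.testing.assert_allclose(got, expected)

    def test_non_finite_rejected(self):
        with pytest.raises(BinningError):
            db.weighted_quantile([1.0, np.nan], [1.0, 1.0], [0.5])


class TestAggregation:
    def test_single_row_identity(self, toy_records):
        one = toy_records.iloc[[3]]
        strata = db.aggregate_person_years(one)
        assert len(strata) == 1
        assert strata.loc[0, "deaths"] == 3
        assert strata.loc[0, "person_years"] == 6

    def test_two_rows_additive(self):
        rows = pd.DataFrame(
            {
                "sex": ["f", "f"], "race": ["w", "w"], "age_group": ["65-69"] * 2,
                "medicaid": [0, 0], "area_id": [1, 1], "year": [2000, 2000],
                "pm25": [8.0, 8.0], "deaths": [1, 2], "person_years": [3, 4],
            }
        )
        strata = db.aggregate_person_years(rows)
        assert len(strata) == 1
        assert strata.loc[0, "deaths"] == 3
        assert strata.loc[0, "person_years"] == 7

    def test_toy_table_against_pandas_tally(self, toy_records):
        strata = db.aggregate_person_years(toy_records)
        keys = ["sex", "race", "age_group", "medicaid", "area_id", "year"]
        oracle = toy_records.groupby(keys)[["deaths", "person_years"]].sum().reset_index()
        assert len(strata) == 4 == len(oracle)
        merged = strata.merge(oracle, on=keys, suffixes=("", "_oracle"))
        assert (merged["deaths"] == merged["deaths_oracle"]).all()
        assert (merged["person_years"] == merged["person_years_oracle"]).all()

    def test_mass_conservation_on_cohort(self, small_cohort):
        strata = db.aggregate_person_years(small_cohort)
        assert strata["deaths"].sum() == small_cohort["deaths"].sum()
        assert strata["person_years"].sum() == small_cohort["person_years"].sum()
        keys = ["sex", "race", "age_group", "medicaid", "area_id", "year"]
        assert not strata.duplicated(keys).any()

    def test_non_constant_column_raises_with_names(self, toy_records):
        bad = toy_records.copy()
        bad.loc[1, "pm25"] = 99.0  # same key as row 0
        with pytest.raises(AggregationError, match="pm25"):
            db.aggregate_person_years(bad)

    def test_missing_key_field(self, toy_records):
        with pytest.raises(AggregationError, match="zip"):
            db.aggregate_person_years(toy_records, key_fields=["zip"])


class TestAssignExposureBins:
    def test_published_decile_boundaries_fixture(self):
        # annual PM2.5 deciles (ug/m3): 10% at 5.80 ... 90% at 13.95
        boundaries = np.array([5.80, 7.28, 8.23, 9.00, 9.75, 10.53, 11.41, 12.46, 13.95])
        d = BinDefinition("pm25", 10, boundaries)
        assert d.assign([5.0])[0] == 1
        assert d.assign([14.5])[0] == 10
        assert d.assign([9.4])[0] == 5

    def test_equal_mass_split_on_four_points(self):
        strata = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0], "deaths": 0, "person_years": [5.0] * 4}
        )
        binned, d = db.assign_exposure_bins(strata, "x", n_bins=2)
        np.testing.assert_array_equal(binned["x_bin"], [1, 1, 2, 2])
        np.testing.assert_allclose(d.bin_person_years, [10.0, 10.0])

    def test_degenerate_single_value(self):
        strata = pd.DataFrame({"x": [3.0] * 8, "deaths": 0, "person_years": 1.0})
        with pytest.raises(BinningError):
            db.assign_exposure_bins(strata, "x", n_bins=2)

    def test_duplicated_cut_points(self):
        strata = pd.DataFrame(
            {"x": [1.0] * 8 + [2.0, 3.0], "deaths": 0, "person_years": 1.0}
        )
        with pytest.raises(BinningError, match="degenerate|distinct"):
            db.assign_exposure_bins(strata, "x", n_bins=5)

    def test_non_finite_exposure(self):
        strata = pd.DataFrame({"x": [1.0, np.inf, 2.0], "deaths": 0, "person_years": 1.0})
        with pytest.raises(BinningError):
            db.assign_exposure_bins(strata, "x", n_bins=2)

    def test_shift_invariance_of_labels(self, small_strata_binned):
        binned, _ = small_strata_binned
        shifted = binned.drop(columns=["pm25_bin"]).copy()
        shifted["pm25"] = shifted["pm25"] + 100.0
        reshifted, _ = db.assign_exposure_bins(shifted, "pm25", n_bins=10)
        np.testing.assert_array_equal(reshifted["pm25_bin"], binned["pm25_bin"])

    def test_mass_balance_within_tolerance(self, small_strata_binned):
        binned, d = small_strata_binned
        total = binned["person_years"].sum()
        tol = max(binned["person_years"].max(), 0.01 * total / d.n_bins)
        assert np.abs(d.bin_person_years - total / d.n_bins).max() <= tol
        assert d.bin_person_years.sum() == total

    def test_equal_count_option(self, small_strata_binned):
        binned, _ = small_strata_binned
        strata = binned.drop(columns=["pm25_bin"])
        by_count, _ = db.assign_exposure_bins(strata, "pm25", n_bins=10, equal_mass=False)
        counts = by_count["pm25_bin"].value_counts()
        assert counts.max() - counts.min() <= max(2, 0.02 * len(strata))


class TestBinSummaries:
    def test_hand_weighted_mean(self):
        strata = pd.DataFrame(
            {
                "x": [8.0, 10.0, 20.0, 30.0],
                "x_bin": [1, 1, 2, 2],
                "deaths": 0,
                "person_years": [1.0, 3.0, 1.0, 1.0],
            }
        )
        d = db.bin_summaries(strata, "x")
        assert d.bin_mean_exposure[0] == pytest.approx((8 * 1 + 10 * 3) / 4)  # 9.5
        assert d.bin_mean_exposure[1] == pytest.approx(25.0)

    def test_single_stratum_per_bin(self):
        strata = pd.DataFrame(
            {"x": [1.0, 5.0, 9.0], "x_bin": [1, 2, 3], "deaths": 0, "person_years": 2.0}
        )
        d = db.bin_summaries(strata, "x")
        np.testing.assert_allclose(d.bin_mean_exposure, [1.0, 5.0, 9.0])

    def test_uniform_weights_equal_unweighted_mean(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        strata = pd.DataFrame({"x": x, "x_bin": [1, 1, 2, 2], "deaths": 0, "person_years": 3.0})
        d = db.bin_summaries(strata, "x")
        np.testing.assert_allclose(d.bin_mean_exposure, [x[:2].mean(), x[2:].mean()])

    def test_empty_bin_errors(self):
        strata = pd.DataFrame({"x": [1.0, 2.0], "x_bin": [1, 3], "deaths": 0, "person_years": 1.0})
        with pytest.raises(BinningError, match="empty"):
            db.bin_summaries(strata, "x")

    def test_means_increase_and_json_round_trip(self, small_strata_binned, tmp_path):
        _, d = small_strata_binned
        assert (np.diff(d.bin_mean_exposure) > 0).all()
        path = tmp_path / "bins.json"
        d.to_json(str(path))
        loaded = BinDefinition.from_json(str(path))
        np.testing.assert_allclose(loaded.boundaries, d.boundaries)
        np.testing.assert_allclose(loaded.bin_mean_exposure, d.bin_mean_exposure)
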