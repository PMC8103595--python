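"""Propensity model, stabilized weights and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest

import dosebin as db
from dosebin.config import GBMConfig
from dosebin.errors import ConfigurationError, EstimationError
from dosebin.weights import PropensityModel, effective_sample_size, weighted_smd

from conftest import fast_gbm


def _stub_model(p_hat: np.ndarray, bins: np.ndarray, n_bins: int) -> PropensityModel:
    """Model whose stored out-of-fold probabilities are fully controlled."""
    n = len(bins)
    proba = np.full((n, n_bins), np.nan)
    proba[np.arange(n), bins - 1] = p_hat
    return PropensityModel(
        exposure="x",
        bin_col="x_bin",
        confounders=[],
        n_bins=n_bins,
        hyper=GBMConfig(),
        oof_proba=proba,
        train_bins=bins.copy(),
    )


class TestStabilizedWeights:
    @pytest.mark.parametrize(
        "n_bins,p_hat,expected_sw",
        [(10, 0.1, 1.0), (10, 0.05, 2.0), (4, 0.25, 1.0)],
    )
    def test_direct_division(self, n_bins, p_hat, expected_sw):
        bins = np.arange(1, n_bins + 1)
        model = _stub_model(np.full(n_bins, p_hat), bins, n_bins)
        strata = pd.DataFrame({"x_bin": bins, "person_years": 1.0})
        wt = db.stabilized_weights(model, strata)
        np.testing.assert_allclose(wt["sw"], expected_sw)

    def test_probability_floor_applied_with_warning(self):
        bins = np.array([1, 2])
        model = _stub_model(np.array([1e-9, 0.5]), bins, 2)
        strata = pd.DataFrame({"x_bin": bins, "person_years": 1.0})
        with pytest.warns(UserWarning, match="floored"):
            wt = db.stabilized_weights(model, strata, probability_floor=1e-6)
        assert wt.loc[0, "sw"] == pytest.approx(0.5 / 1e-6)

    def test_percentile_truncation_flagged(self):
        n = 200
        rng = np.random.default_rng(0)
        p = np.clip(rng.uniform(0.01, 0.4, n), 1e-6, 1)
        bins = rng.integers(1, 11, n)
        model = _stub_model(p, bins, 10)
        strata = pd.DataFrame({"x_bin": bins, "person_years": 1.0})
        with pytest.warns(UserWarning, match="truncated"):
            wt = db.stabilized_weights(model, strata, truncate_percentiles=(5, 95))
        assert wt["truncated"].sum() > 0
        lo, hi = np.percentile(0.1 / p, [5, 95])
        assert wt["sw"].min() >= lo - 1e-12
        assert wt["sw"].max() <= hi + 1e-12


class TestFitPropensity:
    def test_constant_confounder_predicts_class_shares(self):
        rng = np.random.default_rng(1)
        n = 2_000
        bins = rng.integers(1, 5, n)
        strata = pd.DataFrame({"c": 1.0, "x_bin": bins, "person_years": 1.0})
        model = db.fit_propensity(
            strata, "x", ["c"], hyper=fast_gbm(n_folds=1, subsample=1.0)
        )
        proba = model.training_proba(strata)
        shares = np.bincount(bins, minlength=5)[1:] / n
        np.testing.assert_allclose(proba.mean(axis=0), shares, atol=0.02)

    def test_recovers_deterministic_threshold_rule(self):
        rng = np.random.default_rng(2)
        n = 4_000
        z = rng.normal(size=n)
        bins = 1 + (z > np.median(z)).astype(int)
        strata = pd.DataFrame({"z": z, "x_bin": bins, "person_years": 1.0})
        train, test = strata.iloc[: n // 2], strata.iloc[n // 2 :]
        model = db.fit_propensity(train, "x", ["z"], hyper=fast_gbm(n_estimators=100))
        pred = model.predict_proba(test).argmax(axis=1) + 1
        accuracy = (pred == test["x_bin"].to_numpy()).mean()
        assert accuracy > 0.95

    def test_weight_mass_invariance(self):
        rng = np.random.default_rng(3)
        n = 500
        z = rng.normal(size=n)
        bins = 1 + (z > 0).astype(int)
        strata = pd.DataFrame({"z": z, "x_bin": bins, "person_years": 4.0})
        doubled = pd.concat([strata, strata], ignore_index=True)
        doubled["person_years"] = 2.0
        hyper = fast_gbm(n_folds=1, subsample=1.0, min_child_samples=1)
        m1 = db.fit_propensity(strata, "x", ["z"], hyper=hyper)
        m2 = db.fit_propensity(doubled, "x", ["z"], hyper=hyper)
        np.testing.assert_allclose(
            m1.predict_proba(strata), m2.predict_proba(strata), atol=1e-9
        )

    def test_target_exposure_in_confounders_rejected(self, small_strata_binned):
        binned, _ = small_strata_binned
        with pytest.raises(ConfigurationError, match="pm25"):
            db.fit_propensity(binned, "pm25", ["pm25", "o3"], hyper=fast_gbm())

    def test_absent_class_rejected(self):
        strata = pd.DataFrame(
            {"z": np.arange(10.0), "x_bin": [1, 1, 1, 1, 1, 3, 3, 3, 3, 3],
             "person_years": 1.0}
        )
        with pytest.raises(EstimationError, match="absent"):
            db.fit_propensity(strata, "x", ["z"], hyper=fast_gbm())

    def test_one_vs_rest_probabilities_normalized(self):
        rng = np.random.default_rng(4)
        n = 1_000
        z = rng.normal(size=n)
        bins = 1 + np.clip(np.digitize(z, [-0.5, 0.5]), 0, 2)
        strata = pd.DataFrame({"z": z, "x_bin": bins, "person_years": 1.0})
        model = db.fit_propensity(
            strata, "x", ["z"], hyper=fast_gbm(method="one_vs_rest", n_folds=1)
        )
        proba = model.predict_proba(strata)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert ((proba > 0) & (proba < 1)).all()


class TestBalance:
    def test_unit_weights_leave_smd_unchanged(self, small_strata_binned):
        binned, _ = small_strata_binned
        wt = pd.DataFrame(
            {"bin": binned["pm25_bin"], "p_hat": 0.1, "sw": 1.0, "truncated": False}
        )
        report = db.balance_diagnostics(binned, wt, ["temp_warm", "pct_poverty"], "pm25_bin")
        np.testing.assert_allclose(report.table["smd_before"], report.table["smd_after"])
        assert report.weight_summary["sw_py_weighted_mean"] == pytest.approx(1.0)

    def test_two_stratum_hand_computation(self):
        strata = pd.DataFrame(
            {"c": [0.0, 1.0], "x_bin": [1, 2], "deaths": 0, "person_years": [1.0, 1.0]}
        )
        wt = pd.DataFrame({"bin": [1, 2], "p_hat": 0.5, "sw": 1.0, "truncated": False})
        report = db.balance_diagnostics(strata, wt, ["c"], "x_bin")
        # pooled mean 0.5, pooled sd 0.5; bin means 0 and 1 -> SMD -1 and +1
        t = report.table.set_index("bin")
        assert t.loc[1, "smd_before"] == pytest.approx(-1.0)
        assert t.loc[2, "smd_before"] == pytest.approx(1.0)

    def test_constant_confounder_zero_smd(self):
        strata = pd.DataFrame(
            {"c": 7.0, "x_bin": [1, 1, 2, 2], "deaths": 0, "person_years": 1.0}
        )
        wt = pd.DataFrame({"bin": strata["x_bin"], "p_hat": 0.5, "sw": 1.0, "truncated": False})
        report = db.balance_diagnostics(strata, wt, ["c"], "x_bin")
        assert (report.table["smd_before"] == 0).all()
        assert report.table["zero_variance"].all()

    def test_ess_formula_and_bound(self):
        assert effective_sample_size(np.array([1.0, 1.0, 1.0, 1.0])) == pytest.approx(4.0)
        assert effective_sample_size(np.array([2.0, 1.0])) == pytest.approx(9.0 / 5.0)
        w = np.random.default_rng(5).gamma(2.0, 1.0, 100)
        assert effective_sample_size(w) <= 100.0

    def test_weighted_smd_zero_sd(self):
        x = np.ones(4)
        assert weighted_smd(x, np.array([True, True, False, False]), np.ones(4), 0.0) == 0.0

    def test_categorical_confounders_expanded(self, small_strata_binned):
        binned, _ = small_strata_binned
        wt = pd.DataFrame(
            {"bin": binned["pm25_bin"], "p_hat": 0.1, "sw": 1.0, "truncated": False}
        )
        report = db.balance_diagnostics(binned, wt, ["sex", "race"], "pm25_bin")
        names = set(report.table["confounder"])
        assert {"sex=female", "sex=male"} <= names
        assert any(n.startswith("race=") for n in names)
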