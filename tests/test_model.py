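import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import thermoflor as tf
from conftest import make_series


class TestModelSpec:
    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError):
            tf.ModelSpec(include_group_slopes=True, include_learning=False)
        with pytest.raises(ValueError):
            tf.ModelSpec(include_group_slopes=True, include_group_intercepts=False)

    def test_parameter_count(self):
        assert tf.ModelSpec.full().k == 9  # 6 fixed + 2 variance comps + residual
        assert tf.ModelSpec.intercept_only().k == 2
        assert tf.ModelSpec.per_group().k == 4

    def test_nesting(self):
        full = tf.ModelSpec.full()
        red = full.drop(include_group_slopes=False)
        assert red.is_nested_in(full)
        assert not full.is_nested_in(red)


class TestBuildDesign:
    def test_full_design_dimensions(self, series):
        d = tf.build_design(series, tf.ModelSpec.full())
        assert d.X.shape == (216, 6)
        assert d.n_bees == 36
        assert d.colnames == ("intercept", "l", "s_t", "s_c", "c_t", "c_c")

    def test_intercept_only(self, series):
        d = tf.build_design(series, tf.ModelSpec.intercept_only())
        assert d.X.shape[1] == 1
        assert np.all(d.X == 1.0)

    def test_control_row_indicators(self):
        ser = make_series([(0, "control", 10, 0.8), (1, "bar_rewarded", 10, 0.7)])
        d = tf.build_design(ser, tf.ModelSpec.full())
        row = d.X[np.asarray(d.bee_ids)[d.bee_index] == 0][0]
        # columns: intercept, ln(x), T, C, T ln(x), C ln(x)
        assert row == pytest.approx([1.0, math.log(10), 0.0, 1.0, 0.0, math.log(10)])

    def test_unknown_group_rejected(self):
        ser = make_series([(0, "mystery", 10, 0.5)])
        with pytest.raises(ValueError, match="unknown group"):
            tf.build_design(ser, tf.ModelSpec.full())


class TestFitML:
    def test_noiseless_line_recovered_exactly(self):
        rows = [
            (b, "bar_rewarded", x, 0.5 + 0.1 * math.log(x))
            for b in range(4)
            for x in (10, 20, 30, 40, 50, 60)
        ]
        spec = tf.ModelSpec(
            include_group_intercepts=False, include_group_slopes=False,
            include_bee_intercepts=False, include_bee_slopes=False,
        )
        fit = tf.LearningCurveModel(make_series(rows), spec).fit()
        assert fit.params["intercept"] == pytest.approx(0.5, abs=1e-9)
        assert fit.params["l"] == pytest.approx(0.1, abs=1e-9)
        assert fit.sigma2 <= 1e-12

    def test_zero_variance_components_match_ols(self):
        rng = np.random.default_rng(8)
        rows = [
            (b, "bar_rewarded", x, 0.4 + 0.08 * math.log(x) + rng.normal(0, 0.1))
            for b in range(5)
            for x in (10, 20, 30, 40)
        ]
        ser = make_series(rows)
        spec = tf.ModelSpec(
            include_group_intercepts=False, include_group_slopes=False,
            include_bee_intercepts=False, include_bee_slopes=False,
        )
        fit = tf.LearningCurveModel(ser, spec).fit()
        X = np.column_stack([np.ones(len(ser)), np.log(ser.x)])
        beta, rss = np.linalg.lstsq(X, ser.theta, rcond=None)[:2]
        assert np.abs(fit.params.to_numpy() - beta).max() < 1e-8
        n = len(ser)
        llf_ols = -0.5 * n * (math.log(2 * math.pi * rss[0] / n) + 1)
        assert fit.llf == pytest.approx(llf_ols, abs=1e-8)

    def test_noiseless_group_offset_recovered(self):
        offsets = {"bar_rewarded": 0.3, "circle_rewarded": 0.45, "control": 0.6}
        rows = [
            (b, g, x, offsets[g])
            for b, g in enumerate(
                ["bar_rewarded"] * 3 + ["circle_rewarded"] * 3 + ["control"] * 3
            )
            for x in (10, 20, 30)
        ]
        spec = tf.ModelSpec(
            include_learning=False, include_group_slopes=False,
            include_bee_intercepts=False, include_bee_slopes=False,
        )
        fit = tf.LearningCurveModel(make_series(rows), spec).fit()
        assert fit.params["s_c"] == pytest.approx(0.3, abs=1e-9)
        assert fit.params["s_t"] == pytest.approx(0.15, abs=1e-9)

    def test_matches_mixedlm_oracle_random_intercepts(self):
        series = tf.simulate_series(tf.CohortConfig(seed=7, bees_per_group=8))
        spec = tf.ModelSpec.full().drop(include_bee_slopes=False)
        mine = tf.LearningCurveModel(series, spec).fit()
        df = series.copy()
        df["lnx"] = np.log(df.x)
        df["T"] = (df.group == "circle_rewarded").astype(float)
        df["C"] = (df.group == "control").astype(float)
        df["Tlnx"], df["Clnx"] = df["T"] * df.lnx, df["C"] * df.lnx
        oracle = sm.MixedLM(
            df.theta, sm.add_constant(df[["lnx", "T", "C", "Tlnx", "Clnx"]]),
            groups=df.bee_id,
        ).fit(reml=False)
        assert mine.llf == pytest.approx(oracle.llf, abs=1e-6)
        assert np.abs(mine.params.to_numpy() - oracle.fe_params.to_numpy()).max() < 1e-6

    def test_singular_design_names_columns(self):
        # single-group data makes the group indicator columns all-zero
        ser = make_series(
            [(b, "bar_rewarded", x, 0.5) for b in range(3) for x in (10, 20, 30)]
        )
        with pytest.raises(ValueError, match="s_t"):
            tf.LearningCurveModel(ser, tf.ModelSpec.full())

    def test_nested_deviance_monotonicity(self):
        # adding parameters can only improve the maximised likelihood
        chain_steps = [
            {},
            {"include_bee_slopes": False},
            {"include_bee_slopes": False, "include_group_slopes": False},
            {
                "include_bee_slopes": False, "include_group_slopes": False,
                "include_group_intercepts": False,
            },
            {
                "include_bee_slopes": False, "include_group_slopes": False,
                "include_group_intercepts": False, "include_learning": False,
            },
        ]
        for rep in range(50):
            cfg = tf.CohortConfig(
                bees_per_group=4, seed=400 + rep,
                group_slope_shift=0.1 * (rep % 3),
            )
            ser = tf.simulate_series(cfg)
            devs = []
            for drops in chain_steps:
                spec = tf.ModelSpec(**{
                    name: False for name in drops
                }) if drops else tf.ModelSpec.full()
                devs.append(tf.LearningCurveModel(ser, spec).fit().deviance)
            assert all(d1 <= d2 + 1e-6 for d1, d2 in zip(devs, devs[1:])), (
                f"replicate {rep}: deviances not monotone {devs}"
            )


class TestInformationCriteria:
    def test_identity(self, full_fit):
        dev, k, aic = tf.information_criteria(full_fit)
        assert aic == dev + 2 * k
        assert full_fit.aic == pytest.approx(dev + 2 * k)

    def test_delta_arithmetic_of_nested_pairs(self, series):
        full = tf.LearningCurveModel(series, tf.ModelSpec.full()).fit()
        red = tf.LearningCurveModel(
            series, tf.ModelSpec.full().drop(include_group_slopes=False)
        ).fit()
        d_dev = red.deviance - full.deviance
        d_aic = red.aic - full.aic
        d_k = full.k - red.k
        assert d_k == 2
        assert d_aic == pytest.approx(d_dev - 2 * d_k, abs=1e-9)


class TestPredict:
    def test_flat_when_no_slope(self):
        ser = make_series(
            [(b, "bar_rewarded", x, 0.7) for b in range(3) for x in (10, 20, 30)]
        )
        spec = tf.ModelSpec(
            include_learning=False, include_group_intercepts=False,
            include_group_slopes=False, include_bee_slopes=False,
        )
        fit = tf.LearningCurveModel(ser, spec).fit()
        pred = fit.predict("bar_rewarded", [1, 10, 60])
        assert np.allclose(pred.theta, 0.7, atol=1e-6)

    def test_intercept_at_x_equal_one(self, full_fit):
        pred = full_fit.predict("control", [1])
        expected = (
            full_fit.params["intercept"] + full_fit.params["s_c"]
        )
        assert pred.theta.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_monotone_when_total_slope_positive(self, full_fit):
        pred = full_fit.predict("bar_rewarded", np.arange(1, 100))
        total_slope = full_fit.params["l"]
        if total_slope > 0:
            assert (np.diff(pred.theta) >= -1e-12).all()

    def test_summary_mentions_terms(self, full_fit):
        text = full_fit.summary()
        for term in ("intercept", "l", "s_t", "AIC"):
            assert term in text
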