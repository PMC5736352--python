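import math

import numpy as np
import pandas as pd
import pytest

import thermoflor as tf
from thermoflor.simulate import GROUPS


class TestTrueSuccessCurve:
    def test_theta_quarter_pi_gives_half(self):
        bee = tf.BeeParams(intercept_theta=math.pi / 4, learning_rate=0.0)
        assert tf.true_success_curve(bee, 1) == pytest.approx(0.5)
        assert tf.true_success_curve(bee, 37) == pytest.approx(0.5)

    def test_control_parameterisation_flat_at_half(self):
        # no slope anywhere: identical 50% success at visit 10 and 60
        bee = tf.BeeParams(intercept_theta=math.pi / 4)
        assert tf.true_success_curve(bee, 10) == pytest.approx(
            tf.true_success_curve(bee, 60)
        )
        assert tf.true_success_curve(bee, 10) == pytest.approx(0.5)

    def test_closed_form(self):
        bee = tf.BeeParams(intercept_theta=0.6, learning_rate=0.1)
        expected = math.sin(0.6 + 0.1 * math.log(20)) ** 2
        assert tf.true_success_curve(bee, 20) == pytest.approx(expected, abs=1e-12)

    def test_domain_error_below_one(self):
        with pytest.raises(ValueError):
            tf.true_success_curve(tf.BeeParams(), 0)

    def test_monotone_when_slope_positive(self):
        bee = tf.BeeParams(intercept_theta=0.3, learning_rate=0.2)
        xs = np.arange(1, 200)
        p = tf.true_success_curve(bee, xs)
        assert np.all(np.diff(p) >= -1e-12)

    def test_clamped_at_certainty(self):
        bee = tf.BeeParams(intercept_theta=1.0, learning_rate=1.0)
        assert tf.true_success_curve(bee, 1000) == pytest.approx(1.0)


class TestSimulateTrial:
    def test_deterministic_under_seeding(self):
        arena = tf.ArenaConfig.small()
        out = [
            tf.simulate_trial(
                tf.BeeParams(), arena, "control", np.random.default_rng(42)
            )
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(out[0], out[1])

    def test_degenerate_probability_one(self):
        # theta pinned at pi/2: every counted landing is a correct action
        bee = tf.BeeParams(intercept_theta=math.pi / 2, learning_rate=0.0)
        rec = tf.simulate_trial(
            bee, tf.ArenaConfig.small(), "bar_rewarded", np.random.default_rng(0)
        )
        counted = rec[(rec.phase == "learning") & rec.counted]
        assert (counted.probed == counted.rewarding).all()

    def test_counted_totals_exact(self):
        arena = tf.ArenaConfig.large()
        rec = tf.simulate_trial(
            tf.BeeParams(), arena, "circle_rewarded", np.random.default_rng(3)
        )
        counted = rec[rec.counted]
        assert (counted.phase == "learning").sum() == arena.landings_learning
        assert (counted.phase == "test").sum() == arena.landings_test

    def test_visit_index_strictly_increasing_over_counted(self):
        rec = tf.simulate_trial(
            tf.BeeParams(), tf.ArenaConfig.small(), "control", np.random.default_rng(9)
        )
        for _, sub in rec[rec.counted].groupby("phase"):
            assert (np.diff(sub.visit_index) == 1).all()

    def test_control_cohort_pooled_success_near_half(self):
        # 12 bees x 60 landings at p = 0.5: pooled rate within 3 binomial SE
        cfg = tf.CohortConfig(
            groups=("control",), bees_per_group=12,
            sd_bee_intercept=0.0, sd_bee_slope=0.0, seed=5,
        )
        scored = tf.score_dataset(tf.simulate_cohort(cfg))
        learn = scored[scored.phase == "learning"]
        n = len(learn)
        assert n == 720
        se = math.sqrt(0.25 / n)
        assert abs(learn.correct.mean() - 0.5) < 3 * se


class TestSimulateCohort:
    def test_canonical_design_dimensions(self, small_cohort):
        learn = small_cohort[(small_cohort.phase == "learning") & small_cohort.counted]
        assert small_cohort.bee_id.nunique() == 36
        assert len(learn) == 36 * 60
        assert set(small_cohort.group.unique()) == set(GROUPS)

    def test_empty_group_set_rejected(self):
        with pytest.raises(ValueError):
            tf.CohortConfig(groups=())

    def test_zero_bee_spread_shares_one_curve(self):
        cfg = tf.CohortConfig(
            bees_per_group=4, sd_bee_intercept=0.0, sd_bee_slope=0.0, seed=2
        )
        ser = tf.simulate_series(cfg, residual_sd=0.0)
        for _, sub in ser.groupby("group"):
            per_bee = sub.pivot(index="bee_id", columns="x", values="theta")
            assert np.allclose(per_bee.to_numpy(), per_bee.to_numpy()[0], atol=1e-12)

    def test_reward_groups_improve_with_experience(self, series):
        for group in ("bar_rewarded", "circle_rewarded"):
            sub = series[series.group == group]
            early = sub[sub.x == 10].success.mean()
            late = sub[sub.x == 60].success.mean()
            assert late > early + 0.1

    def test_different_seeds_differ(self):
        a = tf.simulate_cohort(tf.CohortConfig(seed=1, bees_per_group=2))
        b = tf.simulate_cohort(tf.CohortConfig(seed=2, bees_per_group=2))
        assert not a.equals(b)


class TestVisitLevelRecovery:
    """Fits to visit-level data converge on the pseudo-true projection.

    Blockwise arcsine success of binomial counts is a slightly biased
    estimate of the generative curve (Jensen bias of arcsin-sqrt at window
    10, log-curvature within blocks), so the estimand of the block-level
    regression is the least-squares projection of the exact block
    expectations, computed here by Poisson-binomial enumeration.
    """

    @staticmethod
    def block_expectation(i, l, b):
        xs = np.arange(10 * (b - 1) + 1, 10 * b + 1)
        ps = np.sin(np.clip(i + l * np.log(xs), 0, math.pi / 2)) ** 2
        pmf = np.array([1.0])
        for p in ps:
            pmf = np.convolve(pmf, [1 - p, p])
        k = np.arange(11)
        return float(pmf @ np.arcsin(np.sqrt(k / 10)))

    def test_mean_estimates_match_projection_oracle(self):
        i_true, l_true = math.pi / 4 - 0.498, 0.216
        blocks = np.arange(1, 7)
        ey = np.array([self.block_expectation(i_true, l_true, b) for b in blocks])
        X = np.column_stack([np.ones(6), np.log(10 * blocks)])
        pseudo = np.linalg.lstsq(X, ey, rcond=None)[0]
        est = []
        for rep in range(60):
            cfg = tf.CohortConfig(
                groups=("bar_rewarded",), bees_per_group=12,
                sd_bee_intercept=0.0, sd_bee_slope=0.0, seed=7000 + rep,
            )
            ser = tf.success_series(tf.simulate_cohort(cfg))
            fit = tf.LearningCurveModel(ser, tf.ModelSpec.per_group()).fit()
            est.append([fit.params["intercept"], fit.params["l"]])
        est = np.asarray(est)
        for j, name in enumerate(("intercept", "l")):
            mcse = est[:, j].std(ddof=1) / math.sqrt(len(est))
            assert abs(est[:, j].mean() - pseudo[j]) <= 3 * mcse, (
                f"{name}: {est[:, j].mean():.4f} vs pseudo-true {pseudo[j]:.4f}"
            )


class TestArenaConfig:
    def test_small_and_large_presets(self):
        small, large = tf.ArenaConfig.small(), tf.ArenaConfig.large()
        assert (small.n_rewarding, small.n_nonrewarding) == (8, 8)
        assert small.refill_policy == "end_of_bout"
        assert (large.n_rewarding, large.n_nonrewarding) == (3, 3)
        assert large.refill_policy == "after_departure"

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            tf.ArenaConfig(n_rewarding=0)
        with pytest.raises(ValueError):
            tf.ArenaConfig(refill_policy="never")
        with pytest.raises(ValueError):
            tf.BeeParams(spatial_bias=1.5)
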