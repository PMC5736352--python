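"""Synthetic bumblebee differential-conditioning data.

Generates visit-level foraging records with the statistical structure the
learning-curve analysis assumes: three test groups (control, circle/cross
rewards, bar rewards), a fixed number of counted landings per bee in the
learning phase (default 60) and test phase (default 20), foraging-bout
structure with feeder depletion and refill rules, and a per-visit success
probability that rises logarithmically with the number of counted visits on
the arcsine scale.

Two generative pathways are provided:

* :func:`simulate_cohort` — the full visit-level simulator (bouts, flower
  choice, depletion, revisit exclusion).  Its output feeds the scoring and
  model-selection machinery end to end.
* :func:`simulate_series` — draws 10-visit block responses directly on the
  arcsine scale with Gaussian residuals, i.e. exactly the process the
  hierarchical learning-curve model describes.  Used for parameter-recovery
  studies where the fitted model must be correctly specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ArenaConfig",
    "BeeParams",
    "CohortConfig",
    "GROUPS",
    "VISIT_COLUMNS",
    "true_success_curve",
    "simulate_trial",
    "simulate_cohort",
    "simulate_series",
]

#: Canonical test-group labels.  ``bar_rewarded`` is the model baseline,
#: ``circle_rewarded`` covers the circle (small-flower) / cross (large-flower)
#: reward contingency, ``control`` has no perceivable temperature pattern.
GROUPS = ("bar_rewarded", "circle_rewarded", "control")

#: Column order of a visit-record dataset (one row per flower landing).
VISIT_COLUMNS = [
    "bee_id",
    "nest_id",
    "group",
    "phase",
    "bout_index",
    "visit_index",
    "flower_id",
    "pattern",
    "rewarding",
    "probed",
    "counted",
]

_HALF_PI = math.pi / 2.0


@dataclass(frozen=True)
class ArenaConfig:
    """Flight-arena layout and bookkeeping rules.

    The small-flower design presents 16 flowers (8 rewarding, 8 not) and
    refills/cleans everything at the end of each foraging bout; the
    large-flower design presents 6 flowers (3 + 3) that are refilled and
    relocated after the bee departs from them.
    """

    flower_size: str = "small"
    n_rewarding: int = 8
    n_nonrewarding: int = 8
    refill_policy: str = "end_of_bout"
    mean_landings_per_bout: float = 10.53
    landings_learning: int = 60
    landings_test: int = 20

    def __post_init__(self) -> None:
        if self.flower_size not in ("small", "large"):
            raise ValueError(f"unknown flower_size {self.flower_size!r}")
        if self.refill_policy not in ("end_of_bout", "after_departure"):
            raise ValueError(f"unknown refill_policy {self.refill_policy!r}")
        for name in ("n_rewarding", "n_nonrewarding", "landings_learning", "landings_test"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_landings_per_bout <= 0:
            raise ValueError("mean_landings_per_bout must be positive")

    @classmethod
    def small(cls, **kwargs) -> "ArenaConfig":
        """The 16-flower arena with end-of-bout refills (mean 10.53 landings/bout)."""
        return cls(**kwargs)

    @classmethod
    def large(cls, **kwargs) -> "ArenaConfig":
        """The 6-flower arena with refill-and-relocate after departure (mean 6.97 landings/bout)."""
        defaults = dict(
            flower_size="large",
            n_rewarding=3,
            n_nonrewarding=3,
            refill_policy="after_departure",
            mean_landings_per_bout=6.97,
        )
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass(frozen=True)
class BeeParams:
    """Generative parameters of one bee's true success curve.

    theta(x) = intercept_theta + learning_rate * ln(x)
               + bee_intercept_dev + bee_slope_dev * ln(x)

    on the arcsine scale, clamped to [0, pi/2]; the per-visit success
    probability is sin^2(theta).  ``spatial_bias`` in [0, 1] tilts flower
    choice toward rewarding positions as bouts progress, emulating spatial
    learning in arenas where flower positions are poorly randomised.
    """

    intercept_theta: float = math.pi / 4.0
    learning_rate: float = 0.0
    bee_intercept_dev: float = 0.0
    bee_slope_dev: float = 0.0
    spatial_bias: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spatial_bias <= 1.0:
            raise ValueError("spatial_bias must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Study-level generative configuration.

    The control group forages at a flat 50% success (theta = pi/4, zero
    slope).  Non-control groups start from the same intercept shifted by
    ``group_intercept_shift`` and learn at ``group_slope_shift`` radians per
    ln(visit).  Defaults put the reward groups at chance over the first
    10-visit block and near 85% success by visit 60 while the control group
    stays at 50% throughout.
    """

    groups: tuple = GROUPS
    bees_per_group: int = 12
    intercept_theta: float = math.pi / 4.0
    group_intercept_shift: float = -0.498
    group_slope_shift: float = 0.216
    sd_bee_intercept: float = 0.10
    sd_bee_slope: float = 0.03
    spatial_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("groups must be non-empty")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if self.bees_per_group < 1:
            raise ValueError("bees_per_group must be >= 1")
        if self.sd_bee_intercept < 0 or self.sd_bee_slope < 0:
            raise ValueError("bee deviation SDs must be non-negative")

    def group_effects(self, group: str) -> tuple[float, float]:
        """(intercept shift, slope) applied on top of ``intercept_theta``."""
        if group == "control":
            return 0.0, 0.0
        return self.group_intercept_shift, self.group_slope_shift


def true_success_curve(
    params: BeeParams,
    x,
    group_intercept_shift: float = 0.0,
    group_slope_shift: float = 0.0,
):
    """Per-visit success probability at counted visit number ``x``.

    theta = intercept + group shift + bee deviation + (slope terms) * ln(x),
    clamped to [0, pi/2]; the probability is sin^2(theta).  Monotone
    non-decreasing in x whenever the total slope is non-negative.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 1):
        raise ValueError("visit number x must be >= 1")
    intercept = params.intercept_theta + group_intercept_shift + params.bee_intercept_dev
    slope = params.learning_rate + group_slope_shift + params.bee_slope_dev
    theta = np.clip(intercept + slope * np.log(x_arr), 0.0, _HALF_PI)
    p = np.sin(theta) ** 2
    return float(p) if np.isscalar(x) or x_arr.ndim == 0 else p


def _bout_length(rng: np.random.Generator, mean: float) -> int:
    """Number of landings in a bout: Poisson truncated at 1."""
    n = int(rng.poisson(mean))
    return max(n, 1)


def _choice_weights(
    rewarding: np.ndarray, bout_index: int, spatial_bias: float
) -> np.ndarray:
    """Flower-choice weights; spatial bias ramps in over the first 6 bouts."""
    w = np.ones(rewarding.size)
    if spatial_bias > 0:
        ramp = min(bout_index / 6.0, 1.0)
        w[rewarding] += spatial_bias * ramp
    return w / w.sum()


def simulate_trial(
    bee: BeeParams,
    arena: ArenaConfig,
    group: str,
    rng: np.random.Generator,
    bee_id: int = 0,
    nest_id: int = 0,
) -> pd.DataFrame:
    """Simulate one bee through the learning phase and the test phase.

    Returns a visit-record dataframe (:data:`VISIT_COLUMNS`) containing both
    counted landings and the uncounted revisits excluded by the arena's
    refill rules.  Counted landings accumulate until the configured totals
    (60 learning / 20 test by default) are reached.

    Bookkeeping follows the experimental protocol: in the small arena a
    flower emptied within a bout stays empty (and revisits to it uncounted)
    until the end-of-bout refill; in the large arena a flower is refilled and
    relocated once the bee lands elsewhere, so only an immediately repeated
    landing on the same flower is uncounted.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    n_flowers = arena.n_rewarding + arena.n_nonrewarding
    flower_rewarding = np.zeros(n_flowers, dtype=bool)
    flower_rewarding[: arena.n_rewarding] = True
    # Pattern display: reward scheme fixed per group; control flowers show none.
    if group == "control":
        patterns = ["none"] * n_flowers
    elif group == "bar_rewarded":
        patterns = ["bar" if r else "circle" for r in flower_rewarding]
    else:
        patterns = ["circle" if r else "bar" for r in flower_rewarding]

    rows: list[tuple] = []

    def run_phase(phase: str, n_counted: int, p_of_x) -> None:
        counted_done = 0
        bout = 0
        emptied = np.zeros(n_flowers, dtype=bool)
        last_flower = -1
        while counted_done < n_counted:
            bout += 1
            if arena.refill_policy == "end_of_bout":
                emptied[:] = False
            weights = _choice_weights(flower_rewarding, bout, bee.spatial_bias)
            for _ in range(_bout_length(rng, arena.mean_landings_per_bout)):
                if counted_done >= n_counted:
                    break
                f = int(rng.choice(n_flowers, p=weights))
                if arena.refill_policy == "after_departure" and f != last_flower:
                    # refilled & relocated while the bee was elsewhere
                    emptied[f] = False
                if arena.refill_policy == "after_departure":
                    counted = f != last_flower or last_flower == -1
                else:
                    counted = not emptied[f]
                if counted:
                    counted_done += 1
                    x = counted_done
                    correct = rng.random() < p_of_x(x)
                    # probed follows from correctness and the scoring designation
                    designated = flower_rewarding[f]
                    probed = bool(designated) == bool(correct)
                else:
                    probed = bool(rng.random() < 0.5)
                if probed and not emptied[f]:
                    emptied[f] = True
                rows.append(
                    (
                        bee_id,
                        nest_id,
                        group,
                        phase,
                        bout,
                        counted_done,
                        f,
                        patterns[f],
                        bool(flower_rewarding[f]) and phase == "learning",
                        probed,
                        counted,
                    )
                )
                last_flower = f
            last_flower = -1  # bee returns to the nest between bouts

    gi, gs = (0.0, 0.0)
    # group effects are folded into BeeParams by the cohort layer; direct
    # callers get the bee's own curve
    run_phase("learning", arena.landings_learning, lambda x: true_success_curve(bee, x, gi, gs))
    # test phase: all wells hold water; performance held at the end-of-learning level
    p_test = true_success_curve(bee, arena.landings_learning, gi, gs)
    run_phase("test", arena.landings_test, lambda x: p_test)

    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


def simulate_cohort(config: CohortConfig, arena: ArenaConfig | None = None) -> pd.DataFrame:
    """Simulate every bee of every test group; returns one visit-record dataframe.

    Bees are assigned round-robin to four nests (the small-flower study drew
    its 36 bees from four nests).  Each bee gets an independent substream of
    the cohort seed, so regenerating a cohort with the same configuration is
    bit-reproducible.
    """
    arena = arena or ArenaConfig.small()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.groups) * config.bees_per_group)
    frames = []
    bee_id = 0
    for group in config.groups:
        gi, gs = config.group_effects(group)
        for _ in range(config.bees_per_group):
            rng = np.random.default_rng(streams[bee_id])
            bee = BeeParams(
                intercept_theta=config.intercept_theta + gi,
                learning_rate=gs,
                bee_intercept_dev=rng.normal(0.0, config.sd_bee_intercept)
                if config.sd_bee_intercept > 0
                else 0.0,
                bee_slope_dev=rng.normal(0.0, config.sd_bee_slope)
                if config.sd_bee_slope > 0
                else 0.0,
                spatial_bias=config.spatial_bias,
            )
            frames.append(
                simulate_trial(bee, arena, group, rng, bee_id=bee_id, nest_id=bee_id % 4)
            )
            bee_id += 1
    return pd.concat(frames, ignore_index=True)


def simulate_series(
    config: CohortConfig,
    xs=(10, 20, 30, 40, 50, 60),
    residual_sd: float = 0.16,
) -> pd.DataFrame:
    """Draw block-level arcsine success directly from the learning-curve model.

    y_nx = theta_group(x) + b_n + r_n * ln(x) + eps, eps ~ N(0, residual_sd^2),
    with b_n, r_n ~ N(0, sd^2) per bee.  This is the data-generating process
    the hierarchical model assumes, so fits to it are correctly specified —
    the generator of choice for parameter-recovery simulations.  The default
    residual SD matches the sampling noise of a 10-visit binomial proportion
    on the arcsine scale (~ 1/(2 sqrt(10))).

    Returns a success-series dataframe: bee_id, group, x, success, theta.
    """
    rng = np.random.default_rng(config.seed)
    xs = np.asarray(xs, dtype=float)
    rows = []
    bee_id = 0
    for group in config.groups:
        gi, gs = config.group_effects(group)
        for _ in range(config.bees_per_group):
            b = rng.normal(0.0, config.sd_bee_intercept) if config.sd_bee_intercept else 0.0
            r = rng.normal(0.0, config.sd_bee_slope) if config.sd_bee_slope else 0.0
            theta = (
                config.intercept_theta
                + gi
                + b
                + (gs + r) * np.log(xs)
                + rng.normal(0.0, residual_sd, size=xs.size)
            )
            theta = np.clip(theta, 0.0, _HALF_PI)
            for x, t in zip(xs, theta):
                rows.append((bee_id, group, int(x), math.sin(t) ** 2, float(t)))
            bee_id += 1
    return pd.DataFrame(rows, columns=["bee_id", "group", "x", "success", "theta"])
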