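"""Stepwise AIC simplification of the learning-curve model family.

The ladder compares the standing best model with a reduction, in a fixed
order: (1) drop the per-bee random slopes r_n; (2) drop the group-by-
experience interactions c_c, c_t; (3) only if step 2 accepted the simpler
model, drop the group terms s_t, s_c; (4) drop the learning slope l.  Each
comparison reports the AIC difference, the deviance change with its
chi-square reference (df = number of parameters removed), and the decision,
which follows AIC: the reduction is accepted unless it raises AIC by more
than ``aic_threshold`` (default 2).

When the interaction step retains the full model, per-group models
y = i + l·ln(x) + b_n are fitted and the effect of experience tested within
each group by removing l.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .model import LearningCurveModel, LearningCurveResults, ModelSpec

__all__ = [
    "ComparisonResult",
    "LadderResult",
    "compare_models",
    "run_ladder",
    "per_group_learning_test",
]

LADDER_STEPS = ("random_slopes", "interactions", "groups", "learning")


@dataclass(frozen=True)
class ComparisonResult:
    """One nested-model comparison in the journal reporting format."""

    name: str
    aic_full: float
    aic_reduced: float
    delta_aic: float
    deviance_change: float
    df: int
    p: float
    decision: str  # keep_full | keep_reduced

    def as_row(self) -> dict:
        return {
            "step": self.name,
            "AIC_full": self.aic_full,
            "AIC_reduced": self.aic_reduced,
            "delta_AIC": self.delta_aic,
            "deviance_change": self.deviance_change,
            "df": self.df,
            "p": self.p,
            "decision": self.decision,
        }


@dataclass
class LadderResult:
    """Ordered comparisons, the final model spec, and every fit along the way."""

    comparisons: list
    final_spec: ModelSpec
    final_fit: LearningCurveResults
    fits: dict

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_row() for c in self.comparisons])

    @property
    def interactions_retained(self) -> bool:
        return any(
            c.name == "interactions" and c.decision == "keep_full"
            for c in self.comparisons
        )


def compare_models(
    fit_full: LearningCurveResults,
    fit_reduced: LearningCurveResults,
    name: str = "comparison",
    aic_threshold: float = 2.0,
) -> ComparisonResult:
    """Compare a fit with a nested reduction of it.

    delta_AIC = AIC_reduced - AIC_full; the deviance change is referred to a
    chi-square with df = number of removed parameters.  The decision follows
    AIC: keep the reduction unless delta_AIC exceeds ``aic_threshold``.
    """
    if not fit_reduced.spec.is_nested_in(fit_full.spec):
        raise ValueError("reduced model is not nested in the full model")
    df = fit_full.k - fit_reduced.k
    if df < 1:
        raise ValueError("models differ by no parameters")
    delta_aic = fit_reduced.aic - fit_full.aic
    dev_change = fit_reduced.deviance - fit_full.deviance
    p = float(stats.chi2.sf(max(dev_change, 0.0), df))
    decision = "keep_reduced" if delta_aic <= aic_threshold else "keep_full"
    return ComparisonResult(
        name=name,
        aic_full=fit_full.aic,
        aic_reduced=fit_reduced.aic,
        delta_aic=delta_aic,
        deviance_change=dev_change,
        df=df,
        p=p,
        decision=decision,
    )


def _fit(series: pd.DataFrame, spec: ModelSpec, rung: str, fits: dict) -> LearningCurveResults:
    key = spec.term_set
    if key not in fits:
        try:
            fits[key] = LearningCurveModel(series, spec).fit()
        except Exception as exc:  # surface which rung failed
            raise RuntimeError(f"model fit failed at ladder rung {rung!r}: {exc}") from exc
    return fits[key]


def run_ladder(
    series: pd.DataFrame,
    aic_threshold: float = 2.0,
    start: ModelSpec | None = None,
) -> LadderResult:
    """Run the stepwise simplification ladder on a success series.

    Steps run strictly in the order random_slopes -> interactions -> groups
    -> learning, each starting from the standing best model; the group step
    runs only if the interaction step accepted the no-interaction model, and
    when interactions are retained the remaining steps are skipped (per-group
    models are then the appropriate follow-up, see
    :func:`per_group_learning_test`).
    """
    if series["group"].nunique() < 2:
        raise ValueError("the ladder's group steps need at least two groups")
    best = start or ModelSpec.full()
    fits: dict = {}
    comparisons: list = []

    def step(name: str, reduced: ModelSpec) -> bool:
        full_fit = _fit(series, best, name, fits)
        red_fit = _fit(series, reduced, name, fits)
        cmp_res = compare_models(full_fit, red_fit, name=name, aic_threshold=aic_threshold)
        comparisons.append(cmp_res)
        return cmp_res.decision == "keep_reduced"

    if step("random_slopes", best.drop(include_bee_slopes=False)):
        best = best.drop(include_bee_slopes=False)

    no_interaction = best.drop(include_group_slopes=False)
    if step("interactions", no_interaction):
        best = no_interaction
        no_groups = best.drop(include_group_intercepts=False)
        if step("groups", no_groups):
            best = no_groups
        no_learning = best.drop(include_learning=False, include_group_slopes=False)
        if step("learning", no_learning):
            best = no_learning

    final_fit = _fit(series, best, "final", fits)
    return LadderResult(
        comparisons=comparisons, final_spec=best, final_fit=final_fit, fits=fits
    )


def per_group_learning_test(
    series: pd.DataFrame, group: str, aic_threshold: float = 2.0
) -> ComparisonResult:
    """Within one group, test whether success changes with experience.

    Fits y = i + l·ln(x) + b_n on that group's series and compares it with
    the slope-free reduction by removing l.
    """
    sub = series[series["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} absent from the series")
    spec = ModelSpec.per_group()
    fit_full = LearningCurveModel(sub, spec).fit()
    fit_reduced = LearningCurveModel(sub, spec.drop(include_learning=False)).fit()
    return compare_models(
        fit_full, fit_reduced, name=f"learning[{group}]", aic_threshold=aic_threshold
    )
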