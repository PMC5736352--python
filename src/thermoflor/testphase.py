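"""Between-group analysis of test-phase foraging success.

Each bee contributes one arcsine-transformed success proportion over its 20
nonrewarding test landings.  Groups are compared by one-way ANOVA (with one
observation per bee this is identical to a model with bee as a random
factor) followed by Tukey HSD pairwise tests summarised as a compact letter
display: groups that are not significantly different share a letter, with
letters assigned in descending order of group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["AnovaResult", "testphase_anova", "tukey_groups", "testphase_summary"]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float

    def __str__(self) -> str:
        return f"F_{self.df_between},{self.df_within} = {self.F:.1f}, p = {self.p:.3g}"


def _check_table(table: pd.DataFrame) -> None:
    counts = table.groupby("group").size()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"groups with fewer than two bees: {list(small.index)}")


def testphase_anova(table: pd.DataFrame, response: str = "theta") -> AnovaResult:
    """One-way ANOVA on the arcsine test-phase success.

    Computed from explicit sums of squares: df_between = groups - 1,
    df_within = bees - groups.  A table with zero between- and within-group
    variation returns F = 0, p = 1.
    """
    _check_table(table)
    y = table[response].to_numpy(dtype=float)
    groups = table["group"].to_numpy()
    labels = np.unique(groups)
    grand = y.mean()
    ss_between = sum(
        (y[groups == g]).size * (y[groups == g].mean() - grand) ** 2 for g in labels
    )
    ss_within = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in labels)
    df_b = len(labels) - 1
    df_w = y.size - len(labels)
    if ss_within <= 0.0:
        if ss_between <= 0.0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=np.inf, df_between=df_b, df_within=df_w, p=0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def tukey_groups(
    table: pd.DataFrame, alpha: float = 0.05, response: str = "theta"
) -> dict:
    """Tukey HSD compact letter display.

    All pairwise comparisons use the studentized-range distribution at the
    ANOVA's within-group df (statsmodels ``pairwise_tukeyhsd``).  Letters are
    assigned insert-absorb style in descending group-mean order starting at
    'a'; the result is invariant to the input ordering of groups.
    """
    _check_table(table)
    y = table[response].to_numpy(dtype=float)
    groups = table["group"].to_numpy()
    means = {g: y[groups == g].mean() for g in np.unique(groups)}
    ordered = sorted(means, key=means.get, reverse=True)

    if all(np.ptp(y[groups == g]) == 0 for g in means) and np.ptp(y) == 0:
        return {g: "a" for g in means}  # fully degenerate table

    hsd = pairwise_tukeyhsd(y, groups, alpha=alpha)
    different = set()
    for (g1, g2), reject in zip(
        ((r[0], r[1]) for r in hsd.summary().data[1:]), hsd.reject
    ):
        if reject:
            different.add(frozenset((str(g1), str(g2))))

    # letter classes = maximal cliques of the not-significantly-different
    # graph (group counts are small, so subset enumeration is exact and cheap)
    from itertools import combinations

    candidates = []
    for r in range(len(ordered), 0, -1):
        for combo in combinations(ordered, r):
            if any(frozenset(pair) in different for pair in combinations(combo, 2)):
                continue
            cset = set(combo)
            if not any(cset <= c for c in candidates):
                candidates.append(cset)
    classes = candidates
    classes.sort(key=lambda c: max(means[g] for g in c), reverse=True)
    letters = {g: "" for g in means}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for g in ordered:
            if g in cls:
                letters[g] += letter
    return letters


def testphase_summary(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-group summary: n, mean raw success, SEM and Tukey letter."""
    anova = testphase_anova(table)
    letters = tukey_groups(table, alpha=alpha)
    rows = []
    for g, sub in table.groupby("group"):
        n = len(sub)
        sem = float(sub["success"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append((g, n, float(sub["success"].mean()), sem, letters[g]))
    out = pd.DataFrame(rows, columns=["group", "n", "mean_success", "sem", "letter"])
    out.attrs["anova"] = anova
    return out
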