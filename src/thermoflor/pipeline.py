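"""End-to-end orchestration: simulate -> score -> model ladder -> test phase -> survey.

`run_pipeline` drives the whole analysis from a flat configuration (YAML or
dict), writing every stage's table as CSV with the seed and a configuration
hash in comment headers, plus a plain-text run log recording package
versions, the seed, and every model comparison.  Reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import config_hash, read_visits, write_csv, write_visits
from .model import ModelSpec
from .scoring import success_series, testphase_table
from .selection import per_group_learning_test, run_ladder
from .simulate import ArenaConfig, CohortConfig, simulate_cohort
from .testphase import testphase_anova, testphase_summary
from .thermal import simulate_survey, survey_summary

__all__ = ["RunConfig", "learning_curve_summary", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat run configuration; see field names for the YAML keys."""

    outdir: str = "thermoflor_run"
    dataset: str | None = None  # load visits from CSV instead of simulating
    flower_size: str = "small"
    bees_per_group: int = 12
    sd_bee_intercept: float = 0.10
    sd_bee_slope: float = 0.03
    spatial_bias: float = 0.0
    window: int = 10
    predictor_transform: str = "ln"
    aic_threshold: float = 2.0
    alpha: float = 0.05
    run_thermal: bool = True
    n_species: int = 118
    detect_threshold: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def arena(self) -> ArenaConfig:
        return ArenaConfig.small() if self.flower_size == "small" else ArenaConfig.large()

    def cohort(self) -> CohortConfig:
        return CohortConfig(
            bees_per_group=self.bees_per_group,
            sd_bee_intercept=self.sd_bee_intercept,
            sd_bee_slope=self.sd_bee_slope,
            spatial_bias=self.spatial_bias,
            seed=self.seed,
        )


def learning_curve_summary(series: pd.DataFrame) -> pd.DataFrame:
    """Figure-style table: per group and block, mean success, SEM and n.

    SEM uses bee as the unit of replication (SD over bees / sqrt(n)); for a
    group with a single bee the SEM is reported missing and a warning is
    printed to stderr.
    """
    if series.empty:
        raise ValueError("empty success series")
    rows = []
    for (group, x), sub in series.groupby(["group", "x"]):
        n = len(sub)
        if n > 1:
            sem = float(sub["success"].std(ddof=1) / np.sqrt(n))
        else:
            sem = np.nan
            print(f"warning: group {group!r} has a single bee; SEM missing", file=sys.stderr)
        rows.append((group, int(x), float(sub["success"].mean()), sem, n))
    return pd.DataFrame(rows, columns=["group", "x", "mean_success", "sem", "n"])


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle as a dict of tables.

    Writes into ``config.outdir``: visits.csv, series.csv,
    learning_summary.csv, ladder.csv, per_group.csv, testphase.csv,
    survey.csv (optional) and run_log.txt.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    settings = {k: v for k, v in asdict(config).items() if k not in ("outdir", "dataset")}
    cfg_hash = config_hash(settings)
    seed = config.seed
    log_lines = [
        f"thermoflor {__version__}",
        f"python {sys.version.split()[0]}",
        f"seed {seed}",
        f"config {cfg_hash}",
    ]

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    arena = config.arena()
    if config.dataset:
        visits = stage("load", lambda: read_visits(config.dataset))
        log_lines.append(f"dataset {config.dataset}")
    else:
        visits = stage("simulate", lambda: simulate_cohort(config.cohort(), arena))
        log_lines.append(
            f"simulated cohort: {config.bees_per_group} bees/group, {config.flower_size} arena"
        )
    write_visits(visits, outdir / "visits.csv", seed=seed, cfg_hash=cfg_hash)

    series = stage("score", lambda: success_series(visits, window=config.window))
    write_csv(series, outdir / "series.csv", seed=seed, cfg_hash=cfg_hash)
    summary = stage("summarise", lambda: learning_curve_summary(series))
    write_csv(summary, outdir / "learning_summary.csv", seed=seed, cfg_hash=cfg_hash)

    ladder = stage(
        "ladder", lambda: run_ladder(series, aic_threshold=config.aic_threshold)
    )
    write_csv(ladder.table(), outdir / "ladder.csv", seed=seed, cfg_hash=cfg_hash)
    for cmp_res in ladder.comparisons:
        log_lines.append(
            f"ladder {cmp_res.name}: dAIC={cmp_res.delta_aic:.3f} "
            f"ddev={cmp_res.deviance_change:.3f} df={cmp_res.df} "
            f"p={cmp_res.p:.4g} -> {cmp_res.decision}"
        )
    log_lines.append(f"final model terms: {', '.join(ladder.final_spec.fixed_terms)}")

    per_group_rows = []
    for group in sorted(series["group"].unique()):
        cmp_res = stage(
            f"per_group[{group}]",
            lambda g=group: per_group_learning_test(
                series, g, aic_threshold=config.aic_threshold
            ),
        )
        per_group_rows.append(cmp_res.as_row())
        log_lines.append(
            f"per-group {group}: dAIC={cmp_res.delta_aic:.3f} "
            f"ddev={cmp_res.deviance_change:.3f} df={cmp_res.df} p={cmp_res.p:.4g}"
        )
    per_group = pd.DataFrame(per_group_rows)
    write_csv(per_group, outdir / "per_group.csv", seed=seed, cfg_hash=cfg_hash)

    tp_table = stage("testphase", lambda: testphase_table(visits))
    anova = testphase_anova(tp_table)
    tp_summary = testphase_summary(tp_table, alpha=config.alpha)
    write_csv(tp_summary, outdir / "testphase.csv", seed=seed, cfg_hash=cfg_hash)
    log_lines.append(f"test-phase ANOVA: {anova}")

    bundle = {
        "visits": visits,
        "series": series,
        "learning_summary": summary,
        "ladder": ladder,
        "per_group": per_group,
        "testphase": tp_summary,
        "anova": anova,
    }

    if config.run_thermal:
        survey = stage(
            "thermal", lambda: simulate_survey(n_species=config.n_species, seed=seed)
        )
        write_csv(survey, outdir / "survey.csv", seed=seed, cfg_hash=cfg_hash)
        summary_s = survey_summary(survey["range_c"], threshold=config.detect_threshold)
        log_lines.append(
            f"survey: {summary_s.n_detectable}/{summary_s.n_species} species "
            f"({summary_s.percent_display}%) >= {summary_s.threshold} C; "
            f"mean {summary_s.mean_range:.2f} sd {summary_s.sd_range:.2f}"
        )
        bundle["survey"] = survey
        bundle["survey_summary"] = summary_s

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return bundle
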