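"""Scoring of flower landings and windowed success rates.

A landing is *correct* in the learning phase when the bee probes a rewarding
flower or withholds probing on a nonrewarding one.  In the test phase every
well holds water, so correctness is judged against the reward scheme of the
preceding learning phase (probing a flower whose pattern had been rewarding
is correct).  Revisits to emptied flowers are excluded before scoring, and
success is summarised in blocks of 10 counted visits on the raw and
arcsine (arcsin sqrt) scales.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .simulate import ArenaConfig

__all__ = [
    "arcsine_transform",
    "score_landing",
    "score_dataset",
    "filter_revisits",
    "windowed_success",
    "success_series",
    "testphase_table",
]

SERIES_COLUMNS = ["bee_id", "group", "x", "success", "theta"]


def arcsine_transform(p, variant: str = "sqrt"):
    """Arcsine-transform a proportion.

    ``variant="sqrt"`` (default) is the variance-stabilising arcsin(sqrt(p)),
    mapping [0, 1] onto [0, pi/2] with inverse sin^2; ``variant="plain"``
    is arcsin(p).
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if variant == "sqrt":
        out = np.arcsin(np.sqrt(arr))
    elif variant == "plain":
        out = np.arcsin(arr)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(out) if np.isscalar(p) else out


def score_landing(record, phase_rule: str, trained_rewarding: bool | None = None) -> bool:
    """Score one counted landing as correct (True) or incorrect.

    ``record`` is any mapping with ``rewarding``, ``probed`` and ``counted``
    fields (e.g. a dataframe row).  For ``phase_rule="test"`` the caller must
    supply ``trained_rewarding`` — whether this flower's pattern was the
    rewarding one during the preceding learning phase — since test-phase
    flowers are all actually nonrewarding.
    """
    if not bool(record["counted"]):
        raise ValueError("cannot score an uncounted landing; filter revisits first")
    probed = bool(record["probed"])
    if phase_rule == "learning":
        rewarding = bool(record["rewarding"])
    elif phase_rule == "test":
        if trained_rewarding is None:
            raise ValueError("test-phase scoring needs the trained reward status")
        rewarding = bool(trained_rewarding)
    else:
        raise ValueError(f"unknown phase rule {phase_rule!r}")
    return probed == rewarding


def _trained_scheme(records: pd.DataFrame) -> dict:
    """Per-bee map flower_id -> was rewarding in the learning phase."""
    learn = records[records["phase"] == "learning"]
    scheme: dict = {}
    for (bee, flower), sub in learn.groupby(["bee_id", "flower_id"]):
        scheme[(bee, flower)] = bool(sub["rewarding"].astype(bool).any())
    return scheme


def score_dataset(records: pd.DataFrame) -> pd.DataFrame:
    """Score every counted landing of a visit-record dataset.

    Returns the counted rows with an added boolean ``correct`` column.
    Test-phase landings are scored by the flower's reward designation in the
    same bee's learning phase.
    """
    scheme = _trained_scheme(records)
    counted = records[records["counted"].astype(bool)].copy()
    correct = np.empty(len(counted), dtype=bool)
    for i, (_, row) in enumerate(counted.iterrows()):
        if row["phase"] == "learning":
            correct[i] = score_landing(row, "learning")
        else:
            trained = scheme.get((row["bee_id"], row["flower_id"]), False)
            correct[i] = score_landing(row, "test", trained_rewarding=trained)
    counted["correct"] = correct
    return counted


def filter_revisits(records: pd.DataFrame, arena: ArenaConfig) -> pd.DataFrame:
    """Recompute counted flags from the landing sequence and refill rules.

    Small arena (end-of-bout refills): a landing on a flower the bee has
    already emptied in the same bout is uncounted.  Large arena (refill and
    relocate after departure): a repeat landing counts only if the bee landed
    elsewhere in between — i.e. immediately consecutive repeats are
    uncounted.  First landings always count.  The operation is idempotent:
    counted flags depend only on the landing order and probed flags.

    Input must be ordered within each bee and phase; visit_index over counted
    rows is renumbered 1..n.
    """
    out = records.reset_index(drop=True).copy()
    counted_col = np.ones(len(out), dtype=bool)
    visit_col = np.zeros(len(out), dtype=int)
    for _, idx in out.groupby(["bee_id", "phase"], sort=False).groups.items():
        sub = out.loc[idx]
        if not sub["bout_index"].is_monotonic_increasing:
            raise ValueError("records must be ordered by bout within each bee and phase")
        emptied: set = set()
        last_flower = None
        last_bout = None
        n_counted = 0
        for pos, row in zip(idx, sub.itertuples(index=False)):
            flower = row.flower_id
            if row.bout_index != last_bout:
                # bout boundary: flowers removed, cleaned and refilled
                emptied.clear()
                last_flower = None
                last_bout = row.bout_index
            if arena.refill_policy == "end_of_bout":
                counted = flower not in emptied
            else:
                if last_flower is not None and flower != last_flower:
                    emptied.discard(flower)  # refilled & relocated meanwhile
                counted = last_flower is None or flower != last_flower
            if bool(row.probed) and flower not in emptied:
                emptied.add(flower)
            counted_col[pos] = counted
            if counted:
                n_counted += 1
            visit_col[pos] = n_counted
            last_flower = flower
    out["counted"] = counted_col
    out["visit_index"] = visit_col
    return out


def windowed_success(scored: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Blockwise success rates for one bee's scored landings.

    Block b covers counted visits (window*(b-1), window*b]; its success is
    the fraction of correct actions in the block.  Landings beyond the last
    full window are dropped.  Returns columns x (block-end visit count),
    success and theta.
    """
    if len(scored) < window:
        raise ValueError(f"need at least {window} counted landings for one window")
    scored = scored.sort_values("visit_index")
    correct = scored["correct"].to_numpy(dtype=float)
    n_blocks = len(correct) // window
    xs = window * np.arange(1, n_blocks + 1)
    success = correct[: n_blocks * window].reshape(n_blocks, window).mean(axis=1)
    return pd.DataFrame(
        {"x": xs, "success": success, "theta": arcsine_transform(success)}
    )


def success_series(
    records: pd.DataFrame, window: int = 10, phase: str = "learning"
) -> pd.DataFrame:
    """Score a visit dataset and window it into a per-bee success series.

    Returns one row per bee per block: bee_id, group, x, success, theta —
    the response table fed to the learning-curve model.
    """
    scored = score_dataset(records)
    scored = scored[scored["phase"] == phase]
    frames = []
    for (bee, group), sub in scored.groupby(["bee_id", "group"], sort=True):
        blocks = windowed_success(sub, window=window)
        blocks.insert(0, "group", group)
        blocks.insert(0, "bee_id", bee)
        frames.append(blocks)
    if not frames:
        raise ValueError(f"no counted {phase!r}-phase landings to window")
    return pd.concat(frames, ignore_index=True)[SERIES_COLUMNS]


def testphase_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-bee overall success in the nonrewarding test phase.

    One row per bee: bee_id, group, success (proportion over the counted
    test landings, 20 in the canonical design) and its arcsine transform.
    """
    scored = score_dataset(records)
    scored = scored[scored["phase"] == "test"]
    if scored.empty:
        raise ValueError("dataset has no counted test-phase landings")
    rows = []
    for (bee, group), sub in scored.groupby(["bee_id", "group"], sort=True):
        p = float(sub["correct"].mean())
        rows.append((bee, group, p, arcsine_transform(p)))
    return pd.DataFrame(rows, columns=["bee_id", "group", "success", "theta"])
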