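"""Plain-text I/O: delimited datasets with seed/config provenance headers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .simulate import VISIT_COLUMNS

__all__ = ["config_hash", "write_csv", "read_csv", "write_visits", "read_visits"]

_BOOL_COLS = ["rewarding", "probed", "counted"]


def config_hash(config: dict) -> str:
    """Stable short hash of a flat configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, seed=None, cfg_hash=None, float_format="%.10g") -> None:
    """Write a dataframe as CSV with `# key=value` provenance comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if cfg_hash is not None:
            fh.write(f"# config={cfg_hash}\n")
        df.to_csv(fh, index=False, float_format=float_format)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_visits(records: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    """Visit records as CSV with the canonical header; booleans as 0/1."""
    out = records[VISIT_COLUMNS].copy()
    for col in _BOOL_COLS:
        out[col] = out[col].astype(int)
    write_csv(out, path, seed=seed, cfg_hash=cfg_hash)


def read_visits(path) -> pd.DataFrame:
    df = read_csv(path)
    missing = set(VISIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"visit dataset missing columns: {sorted(missing)}")
    for col in _BOOL_COLS:
        df[col] = df[col].astype(bool)
    return df[VISIT_COLUMNS]
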