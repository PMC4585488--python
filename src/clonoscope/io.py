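"""Cell-table CSV I/O, configuration files, and run manifests.

The interchange format for cell tables is UTF-8 CSV with a header and '.'
decimal separator; coordinates are written to 0.01 μm, intensities at full
precision.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import pandas as pd
import yaml

from .decoding import channel_columns

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_count_table",
    "write_params_echo",
    "load_yaml_config",
    "sha256_of",
    "write_json_atomic",
]

REQUIRED_COLUMNS = ("cell_id", "x_um", "y_um", "layer")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell table CSV, validating schema and intensity range.

    Requires ``cell_id, x_um, y_um, layer`` plus at least one ``chN``
    intensity column; a header-only file yields an empty table.  Optional
    columns (``z_um, clone_id, section, code, ...``) pass through.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    chans = channel_columns(df)
    if not chans:
        raise ValueError(f"no channel intensity columns (ch1..chK) in {path}")
    for col in chans:
        vals = df[col]
        bad = vals[(vals < 0) | (vals > 255) | vals.isna()]
        if len(bad):
            row = int(bad.index[0]) + 2  # 1-based, counting the header line
            raise ValueError(
                f"intensity out of range [0, 255] in column {col!r} at "
                f"file row {row} of {path}"
            )
    if "clone_id" in df.columns:
        df["clone_id"] = df["clone_id"].astype("Int64")
    return df


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table CSV (coordinates rounded to 0.01 μm)."""
    out = df.copy()
    for col in ("x_um", "y_um", "z_um"):
        if col in out.columns:
            out[col] = out[col].round(2)
    out.to_csv(path, index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a replicate count table CSV: ``layer,group,replicate,count``."""
    df = pd.read_csv(path)
    for col in ("layer", "group", "replicate", "count"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    return df


def write_params_echo(params: dict, path: str | Path) -> None:
    """Echo generator/stage parameters as a plain-text key=value file."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(params):
            fh.write(f"{key}={params[key]}\n")


def load_yaml_config(path: str | Path, allowed_keys: set[str]) -> dict:
    """Load a YAML config mapping, rejecting unknown top-level keys."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(data) - allowed_keys
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in {path}")
    return data


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json_atomic(obj, path: str | Path) -> None:
    """Write JSON via a temp file + rename so readers never see partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
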