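"""Reading and writing localization tables and configs."""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = ["read_localizations", "write_localizations", "load_config", "save_config"]

REQUIRED_COLUMNS = ("x_nm", "y_nm")
NUMERIC_COLUMNS = ("x_nm", "y_nm", "frame", "photons", "sigma_x_nm", "sigma_y_nm",
                   "bg_sd", "snr", "loc_error_nm")


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a localization table as CSV (lossless round trip)."""
    table.to_csv(path, index=False)


def read_localizations(path) -> pd.DataFrame:
    """Read a localization-table CSV, auto-detecting the delimiter.

    Requires at least ``x_nm``/``y_nm`` columns; unknown extra columns are
    preserved. Malformed rows (wrong field count, non-numeric values in
    numeric columns) are rejected with their line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        delim = csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        delim = ","
    if delim != ",":
        log.info("detected %r delimiter in %s", delim, path)

    try:
        table = pd.read_csv(path, sep=delim, on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"{path} lacks required columns {missing}; found {list(table.columns)}")
    for col in NUMERIC_COLUMNS:
        if col not in table.columns:
            continue
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2        # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        table[col] = coerced
    return table


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
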