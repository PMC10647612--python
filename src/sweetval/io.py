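"""Reading and writing the package's table formats.

The interchange format is a long-format UTF-8 CSV with a header row and
columns (analyte, matrix, role, level_mg_per_L, replicate, sample, value,
value_unit, rt_min); ``role`` is one of calibration / spike / blank /
me_solvent / me_matrix / sample.  Reports are JSON (machine) and
Markdown (human).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError
from .simulate import LONG_COLUMNS

ROLES = ("calibration", "spike", "blank", "me_solvent", "me_matrix", "sample")
VALUE_UNITS = ("area", "mg_per_L", "mg_per_kg")
REQUIRED_COLUMNS = ("analyte", "matrix", "role", "level_mg_per_L",
                    "replicate", "value", "value_unit")


def read_long_csv(path) -> pd.DataFrame:
    """Read and schema-check a long-format observation table."""
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    bad_roles = set(df["role"].dropna().unique()) - set(ROLES)
    if bad_roles:
        raise ConfigurationError(f"{path}: unknown roles {sorted(bad_roles)}")
    bad_units = set(df["value_unit"].dropna().unique()) - set(VALUE_UNITS)
    if bad_units:
        raise ConfigurationError(f"{path}: unknown value units {sorted(bad_units)}")
    for col in ("sample", "rt_min"):
        if col not in df.columns:
            df[col] = pd.NA
    return df[LONG_COLUMNS]


def write_long_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_peak_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample", "precursor_mz", "product_mz", "rt_min", "area"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def markdown_table(header: Sequence[str], rows: Sequence[Sequence]) -> str:
    """Render a small GitHub-style Markdown table."""
    def fmt(v):
        if v is None:
            return "-"
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)

    lines = ["| " + " | ".join(map(str, header)) + " |",
             "|" + "|".join("---" for _ in header) + "|"]
    for row in rows:
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines) + "\n"
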