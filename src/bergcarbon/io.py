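"""CSV schemas and validated round-trip I/O for the pipeline tables.

Three tabular formats flow through the pipeline, all plain CSV with a
header row:

* monitoring series — ``year, fastice_duration, scoured_proportion,
  station, depth_band``
* benthic samples  — ``depth, seaice_duration, blue_carbon, site``
* iceberg registry — ``id, area, status, region``

Validation enforces the domain invariants (proportions in [0, 1], sea-ice
durations in [0, 366] days, non-negative stocks and depths, areas above
the 30 km2 giant-iceberg threshold) and reports the offending CSV line
number on failure.  ``write_csv`` then ``read_csv`` is an identity on
valid tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "validate", "read_csv", "write_csv", "roundtrip"]


def _check_range(df, col, lo, hi, errors):
    bad = df.index[(df[col] < lo) | (df[col] > hi)]
    for i in bad:
        errors.append(
            f"line {i + 2}: {col} = {df.loc[i, col]!r} outside [{lo}, {hi}]"
        )


def _validate_monitoring(df: pd.DataFrame, errors: list[str]) -> None:
    _check_range(df, "scoured_proportion", 0.0, 1.0, errors)
    _check_range(df, "fastice_duration", 0.0, 366.0, errors)


def _validate_benthic(df: pd.DataFrame, errors: list[str]) -> None:
    _check_range(df, "depth", 0.0, float("inf"), errors)
    _check_range(df, "seaice_duration", 0.0, 366.0, errors)
    _check_range(df, "blue_carbon", 0.0, float("inf"), errors)


def _validate_registry(df: pd.DataFrame, errors: list[str]) -> None:
    bad = df.index[df["area"] <= 30.0]
    for i in bad:
        errors.append(
            f"line {i + 2}: area = {df.loc[i, 'area']!r} not above the "
            f"30 km2 giant-iceberg threshold"
        )
    valid = {"fasted", "grounded", "roaming-shelf", "roaming-deep"}
    bad = df.index[~df["status"].isin(valid)]
    for i in bad:
        errors.append(f"line {i + 2}: unknown status {df.loc[i, 'status']!r}")


#: schema name -> (required columns, numeric columns, row validator)
SCHEMAS = {
    "monitoring": (
        ["year", "fastice_duration", "scoured_proportion", "station", "depth_band"],
        ["year", "fastice_duration", "scoured_proportion"],
        _validate_monitoring,
    ),
    "benthic": (
        ["depth", "seaice_duration", "blue_carbon", "site"],
        ["depth", "seaice_duration", "blue_carbon"],
        _validate_benthic,
    ),
    "registry": (
        ["id", "area", "status", "region"],
        ["area"],
        _validate_registry,
    ),
}


def validate(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate a table against a named schema; returns the frame.

    Raises ``ValueError`` listing every violation with its CSV line
    number (header = line 1).  An empty table with the right columns is
    valid.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    columns, numeric, checker = SCHEMAS[schema]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{schema} table missing columns: {missing}")
    errors: list[str] = []
    df = df.reset_index(drop=True)
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[coerced.isna() & df[col].notna()]:
            errors.append(f"line {i + 2}: non-numeric {col} = {df.loc[i, col]!r}")
        for i in df.index[df[col].isna()]:
            errors.append(f"line {i + 2}: missing value in {col}")
        df[col] = coerced
    if not errors and len(df):
        checker(df, errors)
    if errors:
        raise ValueError(f"invalid {schema} table:\n  " + "\n  ".join(errors))
    return df


def read_csv(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a pipeline CSV.  Header-only files are fine."""
    df = pd.read_csv(path)
    return validate(df, schema)


def write_csv(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Validate and write a pipeline CSV (no index column)."""
    validate(df, schema)
    df.to_csv(path, index=False)


def roundtrip(df: pd.DataFrame, path: str | Path, schema: str) -> pd.DataFrame:
    """Write then re-read a table; the result equals the input on valid data."""
    write_csv(df, path, schema)
    return read_csv(path, schema)
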