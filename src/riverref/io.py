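"""CSV readers/writers with schema validation.

All tables are plain CSV with ISO-8601 dates.  Validation failures raise
:class:`SchemaError` naming the offending column and, where applicable,
the zero-based row indices.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .analytes import ANALYTES

CATCHMENT_COLUMNS = [
    "id", "biome", "continent", "latitude",
    "crop_pct", "pasture_pct", "urban_pct",
    "forest_pct", "rangeland_pct", "lentic_pct",
    "olsen_p", "pop_density", "slope", "runoff", "pet",
    "area", "population", "permafrost", "excluded",
]

SAMPLE_COLUMNS = ["site_id", "date", "analyte", "concentration"]
DISCHARGE_COLUMNS = ["site_id", "date", "flow"]

LAND_COLUMNS = [
    "crop_pct", "pasture_pct", "urban_pct",
    "forest_pct", "rangeland_pct", "lentic_pct",
]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _bad_rows(mask: pd.Series, column: str, rule: str) -> None:
    if mask.any():
        rows = [int(i) for i in mask.to_numpy().nonzero()[0][:10]]
        raise SchemaError(f"column {column!r} violates {rule} at row(s) {rows}")


def read_catchments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, CATCHMENT_COLUMNS, "catchments")
    _bad_rows(df["olsen_p"] <= 0, "olsen_p", "> 0")
    _bad_rows(df["pop_density"] < 0, "pop_density", ">= 0")
    _bad_rows(df["area"] <= 0, "area", "> 0")
    for col in LAND_COLUMNS:
        _bad_rows((df[col] < 0) | (df[col] > 100), col, "in [0, 100]")
    # small tolerance: shares are stored as floats
    _bad_rows(df[LAND_COLUMNS].sum(axis=1) > 100 + 1e-6, "land classes", "sum <= 100")
    _bad_rows(df["latitude"].abs() > 90, "latitude", "|lat| <= 90")
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    _check_columns(df, SAMPLE_COLUMNS, "samples")
    _bad_rows(df["concentration"] <= 0, "concentration", "> 0")
    _bad_rows(~df["analyte"].isin(ANALYTES), "analyte", f"in {ANALYTES}")
    return df


def read_discharge(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    _check_columns(df, DISCHARGE_COLUMNS, "discharge")
    _bad_rows(df["flow"] < 0, "flow", ">= 0")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
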