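"""CSV schemas and strict round-trip table IO.

Every artifact the pipeline reads or writes has a declared header; readers
reject files whose header deviates (listing missing/unexpected columns),
writers order columns canonically and encode missing values as empty
fields. Dates are ISO-8601.
"""

from __future__ import annotations

import pandas as pd

from .simulate import PANEL_COUNT_COLUMNS
from .weather import FEATURE_COLUMNS

SCHEMAS: dict[str, list[str]] = {
    "weather_daily": [
        "station", "date", "tmin", "tavg", "tmax", "rhum",
        "precip", "wind", "sol_max", "sol_vol",
    ],
    "weather_hourly": ["station", "date", "hour", "temp"],
    "features": ["station", "date", *FEATURE_COLUMNS],
    "panel": ["center", "date", "population", *PANEL_COUNT_COLUMNS, "y_std"],
    "calendar": None,  # date + free rule columns; validated loosely
}

_DATE_COLS = {"date"}


def _check_header(cols, schema_id: str) -> None:
    expected = SCHEMAS[schema_id]
    if expected is None:
        if "date" not in cols:
            raise ValueError(f"schema {schema_id!r}: missing column 'date'")
        return
    missing = [c for c in expected if c not in cols]
    extra = [c for c in cols if c not in expected]
    if missing or extra:
        raise ValueError(
            f"schema {schema_id!r} header mismatch: missing {missing}, unexpected {extra}"
        )


def read_table(path, schema_id: str) -> pd.DataFrame:
    if schema_id not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}")
    df = pd.read_csv(path)
    _check_header(list(df.columns), schema_id)
    for c in _DATE_COLS & set(df.columns):
        df[c] = pd.to_datetime(df[c])
    expected = SCHEMAS[schema_id]
    if expected is not None:
        df = df[expected]
    return df


def write_table(df: pd.DataFrame, path, schema_id: str) -> None:
    if schema_id not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}")
    out = df.copy()
    expected = SCHEMAS[schema_id]
    if expected is not None:
        _check_header(list(out.columns), schema_id)
        out = out[expected]
    for c in _DATE_COLS & set(out.columns):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")
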