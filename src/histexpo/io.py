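"""Delimited-text readers and writers for the pipeline's table schemas.

Everything is plain CSV.  Schemas:

* daily:   site_id, date (ISO-8601), value, flags (semicolon-joined, optional)
* sites:   site_id, lon, lat, region, network
* annual:  site_id, year, value, n_valid, n_scheduled, max_gap_days, included
* covariates: site_id followed by numeric variable columns (header required)
* trend:   year, f, source, calib_intercept, calib_slope
* residences: person_id, location_id, lon, lat, start, end
"""

from __future__ import annotations

import pandas as pd

from .trend import TrendBasis

__all__ = [
    "read_daily", "read_sites", "read_annual", "write_annual",
    "read_covariates", "read_trend", "write_trend", "read_residences",
]


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file missing columns {missing}")


def read_daily(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["site_id", "date", "value"], "daily")
    df["date"] = pd.to_datetime(df["date"])
    if (df["value"].dropna() < 0).any():
        raise ValueError("daily values must be non-negative")
    return df


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["site_id", "lon", "lat"], "sites")
    if ((df["lon"].abs() > 180) | (df["lat"].abs() > 90)).any():
        raise ValueError("site coordinates out of range")
    return df


def read_annual(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["site_id", "year", "value"], "annual")
    if "included" not in df.columns:
        df["included"] = True
    df["included"] = df["included"].astype(bool)
    return df


def write_annual(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["site_id", "year", "value", "n_valid", "n_scheduled",
                        "max_gap_days", "included"] if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns[0] != "site_id":
        raise ValueError("covariates file must have site_id as its first column")
    return df.set_index("site_id")


def read_trend(path) -> TrendBasis:
    return TrendBasis.from_frame(pd.read_csv(path))


def write_trend(trend: TrendBasis, path) -> None:
    trend.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_residences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["person_id", "location_id", "start", "end"], "residences")
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    if (df["start"] >= df["end"]).any():
        raise ValueError("residence intervals must have start < end")
    return df
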