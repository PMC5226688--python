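"""Individual long-term exposure assignment over residence histories.

Cohort participants move; their long-term exposure is the average of the
annual predictions at each address they occupied, weighted by the exact
number of days spent there within the averaging window (calendar-aware, so
leap years carry one extra day).  Gaps in an address history contribute to
neither numerator nor denominator; the covered fraction of the window is
reported so callers can filter people with sparse histories.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

__all__ = ["weighted_longterm_average", "compare_periods"]


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


def _days_per_year(start: dt.date, end_exclusive: dt.date) -> dict[int, int]:
    """Days in [start, end_exclusive) per calendar year."""
    out = {}
    y = start.year
    while dt.date(y, 1, 1) < end_exclusive:
        y_start = max(start, dt.date(y, 1, 1))
        y_end = min(end_exclusive, dt.date(y + 1, 1, 1))
        if y_start < y_end:
            out[y] = (y_end - y_start).days
        y += 1
    return out


def weighted_longterm_average(intervals: pd.DataFrame, annual_predictions: pd.DataFrame,
                              window_start, window_end) -> pd.DataFrame:
    """Residence-time-weighted multi-year average per person.

    ``intervals`` columns: person_id, location_id, start, end (half-open
    [start, end)); ``annual_predictions`` columns: location_id, year,
    pred_ugm3.  The window is inclusive of both dates (so 1980-01-01 to
    2000-12-31 is the 21-year window).  Returns one row per person with
    weighted_avg, coverage_fraction, n_addresses, moved_flag.
    """
    w0 = _as_date(window_start)
    w1 = _as_date(window_end) + dt.timedelta(days=1)  # half-open end
    if w0 >= w1:
        raise ValueError("window_start must precede window_end")
    window_days = (w1 - w0).days
    pred = annual_predictions.set_index(["location_id", "year"])["pred_ugm3"]

    rows = []
    for person, sub in intervals.groupby("person_id"):
        # integer day counts per (location, year) first, so that splitting an
        # interval at the same location is exactly invariant
        day_counts: dict[tuple, int] = {}
        locations = set()
        for _, r in sub.iterrows():
            s = max(_as_date(r["start"]), w0)
            e = min(_as_date(r["end"]), w1)
            if s >= e:
                continue
            locations.add(r["location_id"])
            for year, days in _days_per_year(s, e).items():
                key = (r["location_id"], year)
                day_counts[key] = day_counts.get(key, 0) + days
        num = 0.0
        den = 0
        for key in sorted(day_counts):
            if key not in pred.index:
                raise KeyError(f"no prediction for location {key[0]!r} year {key[1]}")
            num += day_counts[key] * float(pred.loc[key])
            den += day_counts[key]
        if den == 0:
            raise ValueError(f"person {person!r} has no residence days inside the window")
        rows.append({
            "person_id": person,
            "weighted_avg": num / den,
            "coverage_fraction": den / window_days,
            "n_addresses": len(locations),
            "moved_flag": len(locations) > 1,
        })
    return pd.DataFrame(rows)


def compare_periods(longterm: pd.DataFrame, single_year: pd.DataFrame,
                    group_col: str | None = None) -> dict:
    """Compare long-term weighted averages with a single reference year.

    Both inputs need person_id plus a value column (``weighted_avg`` or the
    first non-id numeric column).  Returns Pearson correlation, the OLS line
    of long-term on single-year, and the paired table; with ``group_col``
    (e.g. moved_flag) the statistics are also computed per group.
    """
    def value_col(df):
        for c in df.columns:
            if c != "person_id" and pd.api.types.is_numeric_dtype(df[c]) and c != group_col:
                return c
        raise ValueError("no numeric value column found")

    lt = longterm[["person_id", value_col(longterm)] + ([group_col] if group_col and group_col in longterm else [])]
    lt = lt.rename(columns={value_col(longterm): "longterm"})
    sy = single_year[["person_id", value_col(single_year)]].rename(
        columns={value_col(single_year): "single_year"})
    paired = lt.merge(sy, on="person_id", how="inner")
    if len(paired) < 3:
        raise ValueError("need >= 3 persons present in both tables")

    def stats(df):
        x = df["single_year"].to_numpy(dtype=float)
        y = df["longterm"].to_numpy(dtype=float)
        if np.std(x) < 1e-12 or np.std(y) < 1e-12:
            raise ValueError("constant values; correlation undefined")
        r = float(np.corrcoef(x, y)[0, 1])
        slope, intercept = np.polyfit(x, y, 1)
        return {"correlation": r, "intercept": float(intercept), "slope": float(slope),
                "n": int(len(df)),
                "mean_longterm": float(y.mean()), "mean_single_year": float(x.mean())}

    out = stats(paired)
    out["table"] = paired
    if group_col and group_col in paired.columns:
        out["by_group"] = {g: stats(sub) for g, sub in paired.groupby(group_col) if len(sub) >= 3}
    return out
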