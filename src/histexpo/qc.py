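"""Annual aggregation of daily monitoring records with inclusion criteria.

Daily PM2.5 (or proxy) measurements are collapsed to site-year annual
averages.  A site-year is retained as a model response only when it is
representative of the whole year:

* completeness — at least two-thirds of the scheduled sampling dates for
  that site-year produced a valid measurement, and
* continuity — fewer than 45 consecutive calendar days without a valid
  sample (a 45-day gap excludes; 44 passes).

Visibility (visual-range) records get their own preprocessing first: days
flagged for heavy fog, dust, or precipitation are dropped and the remaining
distances are truncated at 16.093 km (10 miles), the ceiling of the optical
instruments that replaced human-eye observation.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

VISIBILITY_CAP_KM = 16.093
WEATHER_EXCLUSIONS = frozenset({"fog", "dust", "precipitation"})
COMPLETENESS_MIN = 2.0 / 3.0
MAX_GAP_DAYS = 44  # "< 45 consecutive missing days": longest allowed gap

__all__ = [
    "VISIBILITY_CAP_KM",
    "WEATHER_EXCLUSIONS",
    "SamplingSchedule",
    "preprocess_visibility",
    "max_gap_days",
    "compute_annual_average",
    "annual_from_daily",
    "annual_passthrough",
    "assign_region",
]


@dataclasses.dataclass(frozen=True)
class SamplingSchedule:
    """Per-site sampling cadence used as the completeness denominator.

    ``cadence`` is "daily", "1-in-3", "1-in-6", or "custom"; custom schedules
    carry an explicit set of scheduled dates.
    """

    site_id: str
    cadence: str = "daily"
    custom_dates: frozenset | None = None

    def scheduled_dates(self, year: int) -> list[dt.date]:
        start = dt.date(year, 1, 1)
        n_days = 366 if calendar.isleap(year) else 365
        if self.cadence == "daily":
            return [start + dt.timedelta(days=i) for i in range(n_days)]
        if self.cadence == "1-in-3":
            return [start + dt.timedelta(days=i) for i in range(0, n_days, 3)]
        if self.cadence == "1-in-6":
            return [start + dt.timedelta(days=i) for i in range(0, n_days, 6)]
        if self.cadence == "custom":
            if not self.custom_dates:
                raise ValueError("custom schedule requires custom_dates")
            dates = sorted(d for d in self.custom_dates if d.year == year)
            if not dates:
                raise ValueError(f"custom schedule has no dates in {year}")
            return dates
        raise ValueError(f"unknown cadence {self.cadence!r}")


def _parse_flags(value) -> set:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    if isinstance(value, (set, frozenset, list, tuple)):
        return {str(v).strip().lower() for v in value if str(v).strip()}
    return {tok.strip().lower() for tok in str(value).split(";") if tok.strip()}


def preprocess_visibility(daily: pd.DataFrame, cap_km: float = VISIBILITY_CAP_KM) -> pd.DataFrame:
    """Drop weather-flagged days and truncate visual range at ``cap_km``.

    Idempotent: a second application leaves the output unchanged.  Row order
    is preserved.
    """
    if cap_km <= 0:
        raise ValueError("cap_km must be positive")
    flags = daily.get("flags")
    if flags is None:
        keep = pd.Series(True, index=daily.index)
    else:
        keep = ~flags.map(lambda f: bool(_parse_flags(f) & WEATHER_EXCLUSIONS))
    out = daily.loc[keep].copy()
    out["value"] = np.minimum(out["value"].to_numpy(dtype=float), cap_km)
    return out


def max_gap_days(valid_dates: list[dt.date], year: int, gap_mode: str = "full-year") -> int:
    """Longest run of calendar days in ``year`` with no valid sample.

    ``gap_mode="full-year"`` counts the runs before the first and after the
    last sample as gaps; ``"interior"`` counts only runs between samples.
    """
    n_days = 366 if calendar.isleap(year) else 365
    days = sorted({d.toordinal() for d in valid_dates if d.year == year})
    if not days:
        return n_days
    first = dt.date(year, 1, 1).toordinal()
    last = dt.date(year, 12, 31).toordinal()
    gaps = [b - a - 1 for a, b in zip(days, days[1:])]
    if gap_mode == "full-year":
        gaps.append(days[0] - first)
        gaps.append(last - days[-1])
    elif gap_mode != "interior":
        raise ValueError("gap_mode must be 'full-year' or 'interior'")
    return max(gaps, default=0)


def compute_annual_average(daily: pd.DataFrame, schedule: SamplingSchedule, year: int,
                           gap_mode: str = "full-year") -> dict:
    """Aggregate one site-year of daily records to an annual record.

    Returns a dict with keys ``site_id, year, value, n_valid, n_scheduled,
    max_gap_days, included``.  A year with no valid sample is returned with
    ``included=False`` and ``value=NaN`` rather than raising.
    """
    sub = daily.loc[pd.to_datetime(daily["date"]).dt.year == year]
    if sub["site_id"].nunique() > 1:
        raise ValueError("records for compute_annual_average must belong to one site")
    vals = sub["value"].to_numpy(dtype=float)
    dates = pd.to_datetime(sub["date"]).dt.date
    ok = np.isfinite(vals)
    valid_dates = list(dates[ok])
    n_scheduled = len(schedule.scheduled_dates(year))
    n_valid = len(set(valid_dates))
    gap = max_gap_days(valid_dates, year, gap_mode=gap_mode)
    included = (n_valid / n_scheduled >= COMPLETENESS_MIN) and (gap <= MAX_GAP_DAYS)
    value = float(np.mean(vals[ok])) if n_valid else float("nan")
    return {
        "site_id": schedule.site_id,
        "year": int(year),
        "value": value,
        "n_valid": int(n_valid),
        "n_scheduled": int(n_scheduled),
        "max_gap_days": int(gap),
        "included": bool(included) and n_valid > 0,
    }


def annual_from_daily(daily: pd.DataFrame, schedules: dict[str, SamplingSchedule] | None = None,
                      gap_mode: str = "full-year") -> pd.DataFrame:
    """Apply the annual-average criteria to every site-year in a daily table."""
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    rows = []
    for (site, year), sub in daily.groupby([daily["site_id"], daily["date"].dt.year]):
        sched = (schedules or {}).get(site, SamplingSchedule(site))
        rows.append(compute_annual_average(sub, sched, int(year), gap_mode=gap_mode))
    return pd.DataFrame(rows).sort_values(["site_id", "year"]).reset_index(drop=True)


def annual_passthrough(annual: pd.DataFrame) -> pd.DataFrame:
    """Wrap already-aggregated annual data (proxy networks) in the QC schema.

    Provenance counters are left null and every record is marked included.
    """
    out = annual[["site_id", "year", "value"]].copy()
    out["n_valid"] = pd.NA
    out["n_scheduled"] = pd.NA
    out["max_gap_days"] = pd.NA
    out["included"] = True
    return out


def assign_region(sites: pd.DataFrame, lookup: dict[str, str] | None = None,
                  lon_thresholds: list[tuple[float, str]] | None = None) -> pd.DataFrame:
    """Fill the ``region`` column from a lookup table and/or longitude rules.

    The continental-US convention used throughout is three regions — East,
    MountainWest, WestCoast.  An explicit site lookup takes precedence over
    longitude thresholds ``[(min_lon, region), ...]`` (a site gets the region
    of the largest threshold its longitude meets); a site matching neither
    raises.
    """
    out = sites.copy()
    regions = []
    thresholds = sorted(lon_thresholds or [], key=lambda t: t[0], reverse=True)
    for _, row in out.iterrows():
        sid = row["site_id"]
        if lookup and sid in lookup:
            regions.append(lookup[sid])
            continue
        region = None
        for min_lon, name in thresholds:
            if row["lon"] >= min_lon:
                region = name
                break
        if region is None:
            raise ValueError(f"no region rule matches site {sid!r}")
        regions.append(region)
    out["region"] = regions
    return out
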