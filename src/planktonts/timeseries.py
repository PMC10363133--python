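"""Scalar time-series containers, HELCOM seasons, and julian-day climatology.

The observational unit is an irregularly sampled scalar series at one
station (temperature, a nutrient, Chl a, ...).  The seasonal signal is
summarised by pooling all years onto a common 1-365 julian-day axis:
observations falling on the same julian day (in any year) are averaged
first, and a centred circular rolling window then yields a climatological
mean curve with a moving standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HELCOM_SEASONS",
    "SEASON_ORDER",
    "SampleSeries",
    "assign_season",
    "julian_day",
    "collapse_same_day",
    "rolling_climatology",
    "seasonal_mean",
    "read_series_csv",
    "write_series_csv",
]

#: Baltic (HELCOM) season boundaries: winter Jan-Feb, spring Mar-May,
#: summer Jun-Sep, autumn Oct-Dec.
HELCOM_SEASONS: dict[int, str] = {
    1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer", 9: "summer",
    10: "autumn", 11: "autumn", 12: "autumn",
}

SEASON_ORDER: tuple[str, ...] = ("winter", "spring", "summer", "autumn")

DAYS_IN_CLIMATOLOGY_YEAR = 365


def _validate_season_def(season_def: Mapping[int, str]) -> None:
    if sorted(season_def) != list(range(1, 13)):
        raise ValueError("season definition must map every month 1-12 exactly once")


@dataclass
class SampleSeries:
    """One scalar variable observed at one station on irregular dates.

    ``data`` is a float Series indexed by a sorted ``DatetimeIndex``.
    Units are free text but must be nonempty.
    """

    station_id: str
    variable: str
    units: str
    data: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("units must be nonempty")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            self.data = self.data.copy()
            self.data.index = pd.DatetimeIndex(self.data.index)
        self.data = self.data.sort_index().astype(float)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index


def assign_season(date, season_def: Mapping[int, str] = HELCOM_SEASONS) -> str:
    """Season label of a calendar date under the given month->season map."""
    _validate_season_def(season_def)
    ts = pd.Timestamp(date)
    return season_def[ts.month]


def julian_day(date) -> int:
    """Day-of-year on a fixed 365-day axis.

    In leap years Feb 29 maps to day 60 (the same day as Mar 1) and every
    later date shifts back by one, so the codomain is always 1-365.  The
    resulting same-day collision is resolved by :func:`collapse_same_day`.
    """
    ts = pd.Timestamp(date)
    yday = ts.dayofyear
    if ts.is_leap_year and yday > 60:
        yday -= 1
    return int(yday)


def collapse_same_day(series: SampleSeries) -> pd.Series:
    """Average observations sharing a julian day across years.

    Returns a Series indexed by julian day (1-365) holding the arithmetic
    mean of all observations on that day, the pre-averaging step that
    damps the influence of singular heavily-sampled days before the
    rolling climatology is computed.
    """
    days = np.array([julian_day(d) for d in series.dates])
    vals = series.data.to_numpy()
    out = pd.Series(vals).groupby(days).mean()
    out.index.name = "julian_day"
    out.name = series.variable
    return out


def rolling_climatology(series: SampleSeries, window_days: int = 15) -> pd.DataFrame:
    """Circular rolling mean/SD of the collapsed series on the julian axis.

    For each julian day ``d`` the window covers the ``window_days`` julian
    days centred on ``d`` (wrap-around modulo 365, so the curve is
    continuous across the year break).  Each collapsed julian day counts
    once.  Returns a 365-row frame with columns ``rolling_mean``,
    ``rolling_sd`` (sample SD, NaN when fewer than two contributing days)
    and ``n_contributing``.
    """
    if window_days % 2 == 0:
        raise ValueError("window_days must be odd (centred window)")
    half = window_days // 2
    collapsed = collapse_same_day(series)
    values = np.full(DAYS_IN_CLIMATOLOGY_YEAR, np.nan)
    values[collapsed.index.to_numpy() - 1] = collapsed.to_numpy()

    mean = np.full(DAYS_IN_CLIMATOLOGY_YEAR, np.nan)
    sd = np.full(DAYS_IN_CLIMATOLOGY_YEAR, np.nan)
    n = np.zeros(DAYS_IN_CLIMATOLOGY_YEAR, dtype=int)
    offsets = np.arange(-half, half + 1)
    for d in range(DAYS_IN_CLIMATOLOGY_YEAR):
        window = values[(d + offsets) % DAYS_IN_CLIMATOLOGY_YEAR]
        present = window[~np.isnan(window)]
        n[d] = present.size
        if present.size:
            mean[d] = present.mean()
        if present.size >= 2:
            sd[d] = present.std(ddof=1)
    return pd.DataFrame(
        {
            "julian_day": np.arange(1, DAYS_IN_CLIMATOLOGY_YEAR + 1),
            "rolling_mean": mean,
            "rolling_sd": sd,
            "n_contributing": n,
        }
    )


def seasonal_mean(
    series: SampleSeries, season_def: Mapping[int, str] = HELCOM_SEASONS
) -> dict[str, float]:
    """Arithmetic mean of all raw observations per season, pooling years.

    Seasons without observations map to NaN, never to 0.
    """
    _validate_season_def(season_def)
    seasons = [season_def[ts.month] for ts in series.dates]
    grouped = series.data.groupby(np.array(seasons)).mean()
    return {s: float(grouped.get(s, np.nan)) for s in SEASON_ORDER}


def write_series_csv(series: SampleSeries, path, provenance: str | None = None) -> None:
    """Write a series as a two-column CSV (ISO-8601 date, value)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write(f"# station={series.station_id} variable={series.variable} units={series.units}\n")
        fh.write("date,value\n")
        for d, v in series.data.items():
            fh.write(f"{pd.Timestamp(d).date().isoformat()},{v:.10g}\n")


def read_series_csv(path, station_id: str | None = None,
                    variable: str | None = None, units: str | None = None) -> SampleSeries:
    """Read a series CSV written by :func:`write_series_csv`.

    Metadata defaults are recovered from the embedded comment header when
    present; explicit arguments override.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    df = pd.read_csv(path, comment="#", parse_dates=["date"])
    data = pd.Series(df["value"].to_numpy(),
                     index=pd.DatetimeIndex(df["date"]).rename(None))
    return SampleSeries(
        station_id=station_id or meta.get("station", "unknown"),
        variable=variable or meta.get("variable", path.stem),
        units=units or meta.get("units", "unknown"),
        data=data,
    )
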