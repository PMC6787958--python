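"""Site-hour covariate tables: the predictors vocalization models consume.

One row per site x date x hour-of-day, carrying the raw weather draws plus
the derived temporal predictors: trailing 24-hr rain accumulation, absolute
time to the nearest sunrise and sunset (minutes), day of year, days since
the most recent equinox, and the lunar phase.  The table is the single
interchange format between the weather/astronomy layer and the species
models (CSV columns: site_id, date, hour_of_day, day_of_year,
day_of_year_equinox, temperature, wind_speed, rain_accum_24h, lunar_phase,
time_to_sunrise, time_to_sunset).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import solar, weather

__all__ = [
    "Site",
    "default_sites",
    "COVARIATE_COLUMNS",
    "day_of_year_equinox",
    "derive_covariates",
    "build_covariate_table",
]

#: Canonical column order of the exported covariate table.
COVARIATE_COLUMNS = [
    "site_id",
    "date",
    "hour_of_day",
    "day_of_year",
    "day_of_year_equinox",
    "temperature",
    "wind_speed",
    "rain_accum_24h",
    "lunar_phase",
    "time_to_sunrise",
    "time_to_sunset",
]

# Default study-area bounding box: Riverside East Solar Energy Zone,
# Colorado-Sonoran Desert, southeastern California (~33.7 N, -115.4 W).
_AREA_LAT = (33.55, 33.85)
_AREA_LON = (-115.65, -115.15)


@dataclass(frozen=True)
class Site:
    """A monitoring location."""

    site_id: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


def default_sites(n: int = 133, seed: int = 20160101) -> list[Site]:
    """``n`` sites scattered over the default desert study area.

    Deterministic for a given seed; ids are S001..Snnn.
    """
    rng = np.random.default_rng(seed)
    lat = rng.uniform(*_AREA_LAT, n)
    lon = rng.uniform(*_AREA_LON, n)
    return [
        Site(f"S{i + 1:03d}", round(float(lat[i]), 5), round(float(lon[i]), 5))
        for i in range(n)
    ]


def _equinox_before(date: dt.date) -> dt.date:
    """Most recent March 20 / September 22 on or before ``date``."""
    candidates = [
        dt.date(date.year, 3, 20),
        dt.date(date.year, 9, 22),
        dt.date(date.year - 1, 9, 22),
    ]
    return max(c for c in candidates if c <= date)


def day_of_year_equinox(dates) -> np.ndarray:
    """Days since the most recent equinox (Mar 20 / Sep 22), wrapped to 1-183.

    The covariate feeds period-183 sine/cosine terms, so the few calendar
    days by which the Mar-Sep half-year exceeds 183 wrap around harmlessly.
    """
    dates = pd.DatetimeIndex(dates)
    uniq = dates.normalize().unique()
    lut = {}
    for d in uniq:
        days_since = (d.date() - _equinox_before(d.date())).days
        lut[d] = days_since % 183 + 1
    return dates.normalize().map(lut).to_numpy(dtype=np.int64)


def _sunrise_sunset_lookup(
    sites: Sequence[Site], dates: pd.DatetimeIndex
) -> tuple[np.ndarray, np.ndarray, pd.DatetimeIndex]:
    """Sunrise/sunset minutes-of-day arrays over dates padded by one day."""
    padded = pd.date_range(
        dates.min().normalize() - pd.Timedelta(days=1),
        dates.max().normalize() + pd.Timedelta(days=1),
        freq="D",
    )
    doy = padded.dayofyear.to_numpy()
    yl = np.where(padded.is_leap_year, 366, 365)
    lat = np.array([s.latitude for s in sites])[:, None]
    lon = np.array([s.longitude for s in sites])[:, None]
    sr, ss = solar.sunrise_sunset_minutes(lat, lon, doy[None, :], yl[None, :])
    if np.isnan(sr).any() or np.isnan(ss).any():
        raise solar.NoSolarEventError(
            "polar day/night in the requested site-date range"
        )
    return sr, ss, padded


def _nearest_event_minutes(
    event_min: np.ndarray, site_idx: np.ndarray, day_idx: np.ndarray, t_min: np.ndarray
) -> np.ndarray:
    """|t - nearest event| where events recur daily; continuous at midnight.

    ``event_min[site, padded_day]`` are minutes-of-day; ``day_idx`` indexes
    the padded day axis (already offset so day_idx-1 and day_idx+1 exist);
    ``t_min`` is the row's time in minutes from the padded-range origin.
    """
    best = np.full(t_min.shape, np.inf)
    for delta in (-1, 0, 1):
        ev = (day_idx + delta) * 1440.0 + event_min[site_idx, day_idx + delta]
        best = np.minimum(best, np.abs(t_min - ev))
    return best


def derive_covariates(raw: pd.DataFrame, sites: Sequence[Site]) -> pd.DataFrame:
    """Append derived temporal covariates to a raw hourly weather table.

    ``raw`` must have columns site_id, date, hour_of_day, temperature,
    wind_speed, rain (hourly depth, mm) with exactly 24 consecutive hours
    per site-date.  Rain accumulation sums the trailing 24 hourly records
    including the current one (shorter at the start of each site's record).
    Sample times are the top of each hour, local standard time.
    """
    by_id = {s.site_id: s for s in sites}
    unknown = set(raw["site_id"].unique()) - set(by_id)
    if unknown:
        raise ValueError(f"sites missing coordinates: {sorted(unknown)}")

    df = raw.sort_values(["site_id", "date", "hour_of_day"], kind="stable").reset_index(
        drop=True
    )
    dates = pd.DatetimeIndex(df["date"])

    df["day_of_year"] = dates.dayofyear.to_numpy()
    df["day_of_year_equinox"] = day_of_year_equinox(dates)

    df["rain_accum_24h"] = (
        df.groupby("site_id", sort=False)["rain"]
        .rolling(24, min_periods=1)
        .sum()
        .to_numpy()
    )

    site_list = sorted(by_id)
    site_objs = [by_id[s] for s in site_list]
    site_idx = pd.Categorical(df["site_id"], categories=site_list).codes.astype(np.int64)
    sr, ss, padded = _sunrise_sunset_lookup(site_objs, dates)
    day_idx = ((dates.normalize() - padded[0]) / pd.Timedelta(days=1)).astype(np.int64)
    t_min = day_idx * 1440.0 + df["hour_of_day"].to_numpy() * 60.0
    df["time_to_sunrise"] = _nearest_event_minutes(sr, site_idx, day_idx, t_min)
    df["time_to_sunset"] = _nearest_event_minutes(ss, site_idx, day_idx, t_min)

    # One lunar-phase value per date, evaluated at local noon of the study
    # area (phase drifts ~3% of a lunation per day, so sub-day detail is
    # irrelevant to the cos(phase) terms that consume it).
    mean_lon = float(np.mean([s.longitude for s in site_objs]))
    offset = solar.utc_offset_hours(mean_lon)
    uniq = dates.normalize().unique()
    phase_lut = {
        d: solar.lunar_phase(d.to_pydatetime() + dt.timedelta(hours=12 - offset))
        for d in uniq
    }
    df["lunar_phase"] = dates.normalize().map(phase_lut).to_numpy(dtype=float)

    return df[COVARIATE_COLUMNS + ["rain"]]


def build_covariate_table(
    sites: Sequence[Site],
    dates,
    params: Mapping[int, weather.MonthlyWeatherParams] | None = None,
    seed: int | np.random.SeedSequence = 0,
    spinup_days: int = 1,
) -> pd.DataFrame:
    """Simulate weather and derive covariates in one step.

    ``spinup_days`` extra days are simulated before the first requested date
    so the trailing 24-hr rain window is fully populated from the first
    output row; the spin-up rows are dropped from the result.
    """
    dates = pd.DatetimeIndex(dates).normalize()
    start = dates.min() - pd.Timedelta(days=spinup_days)
    full = pd.date_range(start, dates.max(), freq="D")
    raw = weather.simulate_weather(sites, full, params=params, seed=seed)
    cov = derive_covariates(raw, sites)
    keep = pd.DatetimeIndex(cov["date"]).isin(set(dates))
    return cov.loc[keep].reset_index(drop=True)
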