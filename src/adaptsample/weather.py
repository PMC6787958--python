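"""Seeded synthetic hourly weather for a desert monitoring area.

The generator stands in for an hourly weather feed.  It is parameterized by
monthly summary statistics (mean / sd / min / max for temperature and wind,
mean / max for 24-hr rain accumulation) of the kind a monitoring program
can compute from any nearby station record:

* **temperature** — monthly mean, plus a deterministic diurnal sinusoid
  (coolest in the pre-dawn hours, warmest mid-afternoon), plus Gaussian
  noise, clipped to the monthly [min, max] envelope.  The configured
  monthly sd is the sd of *realized hourly* temperatures, so it is split
  between the two components: a fraction ``DIURNAL_VARIANCE_FRACTION`` of
  the variance goes to the sinusoid (amplitude ``sd * sqrt(2 f)``) and the
  rest to the noise.  This keeps both the monthly mean and sd on target
  and makes clipping a > 3.5-sigma event;
* **wind speed** — Gamma-distributed with the monthly mean and sd (support
  is naturally non-negative, so the configured mean is preserved exactly),
  clipped to the monthly maximum;
* **rain** — zero-inflated and storm-clustered: each site-day is a storm
  day with a small monthly probability; a storm is a contiguous spell of
  six wet hours whose depths are exponential with mean ``rain24_max / 8``.
  The storm-day probability is solved from the monthly mean,
  ``p_storm = rain24_mean / (6 * depth_mean)``, so the expected hourly
  depth equals ``rain24_mean / 24`` while a single storm accumulates
  about three quarters of the monthly maximum — keeping both the mean and
  the order of the maxima on target.  Unclustered per-hour events would
  match the mean but spread rain over several-fold too many distinct wet
  24-h windows and could never approach the tabulated maxima.

Hours are independent across sites; no spatial correlation is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyWeatherParams",
    "default_monthly_params",
    "load_monthly_params",
    "simulate_weather",
    "DIURNAL_PEAK_HOUR",
]

#: Clock hour (local standard) of the diurnal temperature maximum.
DIURNAL_PEAK_HOUR = 15.0

#: Share of the monthly hourly-temperature variance carried by the
#: deterministic diurnal cycle (the rest is hour-to-hour noise).
DIURNAL_VARIANCE_FRACTION = 0.6

#: Wet-hour depths are exponential with mean ``rain24_max / RAIN_EVENT_SCALE``.
RAIN_EVENT_SCALE = 8.0

#: Length of a storm's contiguous wet spell, hours.
STORM_SPELL_HOURS = 6


@dataclass(frozen=True)
class MonthlyWeatherParams:
    """Monthly weather summary statistics driving the generator.

    Temperatures in deg C, wind in km/hr, rain in mm (24-hr accumulation).
    """

    month: int
    temp_mean: float
    temp_sd: float
    temp_min: float
    temp_max: float
    wind_mean: float
    wind_sd: float
    wind_min: float
    wind_max: float
    rain24_mean: float
    rain24_sd: float
    rain24_max: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1-12, got {self.month}")
        if self.temp_sd < 0 or self.wind_sd < 0 or self.rain24_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not self.temp_min <= self.temp_mean <= self.temp_max:
            raise ValueError("need temp_min <= temp_mean <= temp_max")
        if not self.wind_min <= self.wind_mean <= self.wind_max:
            raise ValueError("need wind_min <= wind_mean <= wind_max")
        if min(self.rain24_mean, self.rain24_max) < 0:
            raise ValueError("rain parameters must be >= 0")

    @property
    def diurnal_amplitude(self) -> float:
        """Amplitude of the diurnal sinusoid (deg C).

        Chosen so the sinusoid carries :data:`DIURNAL_VARIANCE_FRACTION`
        of the configured hourly variance (a sinusoid of amplitude A has
        variance A**2 / 2 over the day).
        """
        return self.temp_sd * float(np.sqrt(2.0 * DIURNAL_VARIANCE_FRACTION))

    @property
    def noise_sd(self) -> float:
        """Hour-to-hour temperature noise sd (deg C)."""
        return self.temp_sd * float(np.sqrt(1.0 - DIURNAL_VARIANCE_FRACTION))


def load_monthly_params(source) -> dict[int, MonthlyWeatherParams]:
    """Read monthly weather parameters from a CSV path or file-like object."""
    df = pd.read_csv(source)
    required = {f.name for f in MonthlyWeatherParams.__dataclass_fields__.values()}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weather parameter table missing columns: {sorted(missing)}")
    params = {
        int(row.month): MonthlyWeatherParams(
            **{name: (int(row.month) if name == "month" else float(getattr(row, name)))
               for name in required}
        )
        for row in df.itertuples(index=False)
    }
    if set(params) != set(range(1, 13)):
        raise ValueError("weather parameter table must cover months 1-12 exactly")
    return params


def default_monthly_params() -> dict[int, MonthlyWeatherParams]:
    """Monthly parameters for the default Sonoran-desert study area."""
    ref = resources.files("adaptsample.data") / "monthly_weather.csv"
    with ref.open("r") as fh:
        return load_monthly_params(fh)


def diurnal_cycle(hour, amplitude):
    """Deterministic diurnal temperature anomaly (zero mean over 24 h)."""
    return amplitude * np.cos(
        2.0 * np.pi * (np.asarray(hour, dtype=float) - DIURNAL_PEAK_HOUR) / 24.0
    )


def _site_ids(sites: Sequence) -> list[str]:
    return [s if isinstance(s, str) else s.site_id for s in sites]


def simulate_weather(
    sites: Sequence,
    dates,
    params: Mapping[int, MonthlyWeatherParams] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate hourly weather for every site-hour in ``sites`` x ``dates``.

    Parameters
    ----------
    sites
        Site objects (or bare site-id strings).
    dates
        Anything ``pd.DatetimeIndex`` accepts; one row per site, date, hour.
    params
        Month -> :class:`MonthlyWeatherParams`; defaults to the shipped
        desert parameter table.  All 12 months must be present.
    seed
        Seed (or SeedSequence) making the table bit-reproducible.

    Returns
    -------
    DataFrame with columns site_id, date, hour_of_day, temperature,
    wind_speed, rain (hourly depth, mm), sorted by site, date, hour.
    """
    if params is None:
        params = default_monthly_params()
    missing = set(range(1, 13)) - set(params)
    if missing:
        raise ValueError(f"weather parameters missing for months {sorted(missing)}")

    ids = _site_ids(sites)
    dates = pd.DatetimeIndex(dates).normalize()
    hours = np.arange(24)

    n_sites, n_dates = len(ids), len(dates)
    n = n_sites * n_dates * 24
    site_col = np.repeat(ids, n_dates * 24)
    date_col = np.tile(np.repeat(dates.values, 24), n_sites)
    hour_col = np.tile(hours, n_sites * n_dates)

    month = np.tile(np.repeat(dates.month.values, 24), n_sites)
    by_month = {m: params[m] for m in range(1, 13)}

    def month_field(attr):
        lut = np.array([getattr(by_month[m], attr) for m in range(1, 13)])
        return lut[month - 1]

    rng = np.random.default_rng(seed)

    t_mean = month_field("temp_mean")
    t_sd = month_field("temp_sd")
    amp = t_sd * np.sqrt(2.0 * DIURNAL_VARIANCE_FRACTION)
    noise_sd = t_sd * np.sqrt(1.0 - DIURNAL_VARIANCE_FRACTION)
    temperature = (
        t_mean + diurnal_cycle(hour_col, amp) + rng.normal(0.0, 1.0, n) * noise_sd
    )
    temperature = np.clip(temperature, month_field("temp_min"), month_field("temp_max"))

    w_mean = month_field("wind_mean")
    w_sd = month_field("wind_sd")
    with np.errstate(divide="ignore", invalid="ignore"):
        shape = np.where(w_sd > 0, (w_mean / np.where(w_sd > 0, w_sd, 1.0)) ** 2, 1.0)
        scale = np.where(w_sd > 0, w_sd**2 / np.where(w_mean > 0, w_mean, 1.0), 0.0)
    wind = np.where(
        (w_sd > 0) & (w_mean > 0),
        rng.gamma(np.maximum(shape, 1e-12), np.maximum(scale, 1e-12), n),
        w_mean,
    )
    wind = np.clip(wind, 0.0, month_field("wind_max"))

    r24_mean = month_field("rain24_mean")
    r24_max = month_field("rain24_max")
    depth_mean = np.where(r24_max > 0, r24_max / RAIN_EVENT_SCALE, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_storm = np.where(
            depth_mean > 0,
            np.clip(
                (r24_mean / 24.0) * 24.0 / (STORM_SPELL_HOURS * depth_mean),
                0.0,
                1.0,
            ),
            0.0,
        )
    # one storm-day and spell-start draw per site-date (hour rows are
    # day-contiguous); the spell is a contiguous block of wet hours
    n_days_total = n // 24
    storm_day = (rng.random(n_days_total) < p_storm[::24]).repeat(24)
    spell_start = rng.integers(
        0, 24 - STORM_SPELL_HOURS + 1, n_days_total
    ).repeat(24)
    in_spell = (hour_col >= spell_start) & (hour_col < spell_start + STORM_SPELL_HOURS)
    depth = rng.exponential(1.0, n) * depth_mean
    rain = np.where(storm_day & in_spell, depth, 0.0)

    return pd.DataFrame(
        {
            "site_id": site_col,
            "date": date_col,
            "hour_of_day": hour_col.astype(np.int64),
            "temperature": temperature,
            "wind_speed": wind,
            "rain": rain,
        }
    )
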