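"""Solar and lunar astronomy for acoustic-survey covariates.

Sunrise/sunset are computed from standard solar geometry: the Fourier-series
approximations of Spencer (1971) for solar declination and the equation of
time, combined with the hour-angle sunrise equation at the conventional
zenith of 90.833 degrees (refraction plus solar radius).  Accuracy is within
a few minutes of ephemeris values at mid-latitudes, which is ample for
hour-scale scheduling.

All clock times are local *standard* time: the UTC offset is the site's
nearest 15-degree meridian (``round(longitude / 15)``); daylight-saving
shifts are deliberately ignored, being a clock artifact with no biological
meaning.

The lunar phase is the fractional part of the lunation number: 0 at new
moon, 0.5 at full moon, computed from a fixed reference new moon
(2000-01-06 18:14 UTC) and a mean synodic month of 29.530588 days.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np

#: Mean synodic month, days.
SYNODIC_MONTH = 29.530588

#: Reference new moon (UTC): 2000-01-06 18:14.
NEW_MOON_EPOCH = dt.datetime(2000, 1, 6, 18, 14)

# Zenith angle at sunrise/sunset: 90 deg plus atmospheric refraction (34')
# plus the solar semidiameter (16').
_SUNRISE_ZENITH_DEG = 90.833


class NoSolarEventError(ValueError):
    """The sun does not rise or set on this date (polar day or night)."""


def utc_offset_hours(longitude: float) -> int:
    """Integer standard-time UTC offset for a longitude (nearest meridian)."""
    return int(round(longitude / 15.0))


def _fractional_year(day_of_year, year_length):
    # Angle of the Earth's orbital position, radians; hour fixed at 12h.
    return 2.0 * np.pi * (day_of_year - 1 + 0.5) / year_length


def solar_declination(day_of_year, year_length=365):
    """Solar declination in radians (Spencer 1971 Fourier series)."""
    g = _fractional_year(np.asarray(day_of_year, dtype=float), year_length)
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.001480 * np.sin(3 * g)
    )


def equation_of_time(day_of_year, year_length=365):
    """Equation of time in minutes (Spencer 1971 Fourier series)."""
    g = _fractional_year(np.asarray(day_of_year, dtype=float), year_length)
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def sunrise_sunset_minutes(latitude, longitude, day_of_year, year_length=365):
    """Sunrise and sunset as minutes after local standard midnight.

    Vectorized over ``day_of_year`` (and broadcastable lat/lon).  Returns a
    pair of float arrays; entries are NaN where the sun never crosses the
    horizon (polar day/night).
    """
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    lon = np.asarray(longitude, dtype=float)
    doy = np.asarray(day_of_year, dtype=float)

    decl = solar_declination(doy, year_length)
    eot = equation_of_time(doy, year_length)

    cos_ha = (
        np.cos(np.deg2rad(_SUNRISE_ZENITH_DEG)) - np.sin(lat) * np.sin(decl)
    ) / (np.cos(lat) * np.cos(decl))
    with np.errstate(invalid="ignore"):
        ha_deg = np.rad2deg(np.arccos(np.clip(cos_ha, -1.0, 1.0)))
    ha_deg = np.where(np.abs(cos_ha) > 1.0, np.nan, ha_deg)

    offset_min = np.round(lon / 15.0) * 60.0
    noon = 720.0 - 4.0 * lon - eot + offset_min  # local standard minutes
    return noon - 4.0 * ha_deg, noon + 4.0 * ha_deg


def _year_length(year: int) -> int:
    return 366 if (year % 4 == 0 and year % 100 != 0) or year % 400 == 0 else 365


def solar_events(site, date: dt.date) -> tuple[dt.datetime, dt.datetime]:
    """Sunrise and sunset for one site and date, in local standard time.

    Parameters
    ----------
    site
        Object with ``latitude`` and ``longitude`` attributes (decimal deg).
    date
        Calendar date.

    Returns
    -------
    (sunrise, sunset) : pair of naive datetimes (local standard time).

    Raises
    ------
    NoSolarEventError
        If the sun neither rises nor sets (polar latitudes only).
    """
    doy = date.timetuple().tm_yday
    sr, ss = sunrise_sunset_minutes(
        site.latitude, site.longitude, doy, _year_length(date.year)
    )
    if np.isnan(sr) or np.isnan(ss):
        raise NoSolarEventError(
            f"no sunrise/sunset at latitude {site.latitude} on {date}"
        )
    midnight = dt.datetime.combine(date, dt.time())
    return (
        midnight + dt.timedelta(minutes=float(sr)),
        midnight + dt.timedelta(minutes=float(ss)),
    )


def lunar_phase(when: dt.datetime) -> float:
    """Fraction of the lunation in [0, 1): 0 new moon, 0.5 full moon.

    ``when`` is a naive datetime interpreted as UTC.  Sub-percent accuracy
    against true ephemerides, which suffices because downstream models use
    only the cosine of the phase.
    """
    days = (when - NEW_MOON_EPOCH).total_seconds() / 86400.0
    return float(math.fmod(days / SYNODIC_MONTH, 1.0) % 1.0)
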