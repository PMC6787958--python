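"""Independent test oracles.

The sunrise/sunset oracle follows the NOAA solar-calculation spreadsheet
(Julian-century polynomial ephemeris: geometric mean longitude/anomaly,
equation of center, apparent longitude, corrected obliquity), an algorithm
distinct from the Fourier-series geometry used by the package.
"""

from __future__ import annotations

import datetime as dt
from math import acos, asin, cos, degrees, radians, sin, tan


def noaa_sunrise_sunset(
    latitude: float, longitude: float, date: dt.date, tz_offset_hours: int
) -> tuple[float, float]:
    """Sunrise and sunset in minutes after local midnight (NOAA spreadsheet).

    Longitude positive east; ``tz_offset_hours`` is the local standard-time
    UTC offset.
    """
    # Julian day at local noon.
    a = (14 - date.month) // 12
    y = date.year + 4800 - a
    m = date.month + 12 * a - 3
    jdn = (
        date.day
        + (153 * m + 2) // 5
        + 365 * y
        + y // 4
        - y // 100
        + y // 400
        - 32045
    )
    jd = jdn + 0.5 - tz_offset_hours / 24.0  # 12:00 local standard, as JD
    jc = (jd - 2451545.0) / 36525.0

    gmls = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    eeo = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eoc = (
        sin(radians(gmas)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + sin(radians(2 * gmas)) * (0.019993 - 0.000101 * jc)
        + sin(radians(3 * gmas)) * 0.000289
    )
    stl = gmls + eoc
    sal = stl - 0.00569 - 0.00478 * sin(radians(125.04 - 1934.136 * jc))
    moe = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    oc = moe + 0.00256 * cos(radians(125.04 - 1934.136 * jc))
    decl = degrees(asin(sin(radians(oc)) * sin(radians(sal))))
    vary = tan(radians(oc / 2.0)) ** 2
    eot = 4.0 * degrees(
        vary * sin(2.0 * radians(gmls))
        - 2.0 * eeo * sin(radians(gmas))
        + 4.0 * eeo * vary * sin(radians(gmas)) * cos(2.0 * radians(gmls))
        - 0.5 * vary * vary * sin(4.0 * radians(gmls))
        - 1.25 * eeo * eeo * sin(2.0 * radians(gmas))
    )
    cos_ha = cos(radians(90.833)) / (
        cos(radians(latitude)) * cos(radians(decl))
    ) - tan(radians(latitude)) * tan(radians(decl))
    ha = degrees(acos(cos_ha))
    solar_noon = 720.0 - 4.0 * longitude - eot + tz_offset_hours * 60.0
    return solar_noon - 4.0 * ha, solar_noon + 4.0 * ha
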