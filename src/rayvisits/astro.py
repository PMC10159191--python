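"""Solar and lunar ephemeris helpers.

Low-precision algorithms sufficient for diel classification and lunar-phase
covariates in telemetry work: NOAA's solar-position equations for sunrise and
sunset (accurate to ~1 min at mid latitudes) and a truncated Meeus series for
the illuminated fraction of the lunar disc (accurate to ~0.3%).
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "sunrise_sunset",
    "moon_fraction",
    "season_boundaries",
    "SOLSTICE_EQUINOX_UTC",
]

_SUN_ZENITH_DEG = 90.833  # official sunrise/sunset: refraction + solar radius


def _julian_day(t: dt.datetime) -> float:
    """Julian day number (UT) for a timezone-aware or naive-UTC datetime."""
    if t.tzinfo is not None:
        t = t.astimezone(dt.timezone.utc).replace(tzinfo=None)
    y, m = t.year, t.month
    day = (
        t.day
        + (t.hour + t.minute / 60.0 + t.second / 3600.0) / 24.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + day + b - 1524.5


def _sun_declination_eqtime(jd: float) -> tuple[float, float]:
    """Solar declination (radians) and equation of time (minutes)."""
    t = (jd - 2451545.0) / 36525.0
    l0 = np.deg2rad((280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0)
    m = np.deg2rad(357.52911 + t * (35999.05029 - 0.0001537 * t))
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    c = (
        np.sin(m) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * m) * (0.019993 - 0.000101 * t)
        + np.sin(3 * m) * 0.000289
    )
    true_long = l0 + np.deg2rad(c)
    omega = np.deg2rad(125.04 - 1934.136 * t)
    app_long = true_long - np.deg2rad(0.00569 + 0.00478 * np.sin(omega))
    eps0 = np.deg2rad(
        23.0 + (26.0 + (21.448 - t * (46.8150 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    )
    eps = eps0 + np.deg2rad(0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(eps) * np.sin(app_long))
    y = np.tan(eps / 2.0) ** 2
    eqtime = 4.0 * np.rad2deg(
        y * np.sin(2 * l0)
        - 2 * e * np.sin(m)
        + 4 * e * y * np.sin(m) * np.cos(2 * l0)
        - 0.5 * y * y * np.sin(4 * l0)
        - 1.25 * e * e * np.sin(2 * m)
    )
    return float(decl), float(eqtime)


def sunrise_sunset(
    date: dt.date, latitude: float, longitude: float
) -> tuple[dt.datetime, dt.datetime]:
    """Sunrise and sunset as UTC datetimes for a calendar date and position.

    Raises ``ValueError`` for polar day/night (sun never crosses the official
    zenith), which cannot define a diel window.
    """
    noon_guess = dt.datetime(date.year, date.month, date.day, 12, 0, 0)
    jd = _julian_day(noon_guess) - longitude / 360.0
    out = []
    for rise in (True, False):
        decl, eqtime = _sun_declination_eqtime(jd)
        lat = np.deg2rad(latitude)
        cos_ha = (
            np.cos(np.deg2rad(_SUN_ZENITH_DEG)) / (np.cos(lat) * np.cos(decl))
            - np.tan(lat) * np.tan(decl)
        )
        if not -1.0 <= cos_ha <= 1.0:
            raise ValueError(
                f"sun does not rise/set at latitude {latitude} on {date} "
                "(polar day or night)"
            )
        ha = np.rad2deg(np.arccos(cos_ha))
        if not rise:
            ha = -ha
        minutes_utc = 720.0 - 4.0 * (longitude + ha) - eqtime
        t = dt.datetime(
            date.year, date.month, date.day, tzinfo=dt.timezone.utc
        ) + dt.timedelta(minutes=float(minutes_utc))
        # one refinement pass with the declination at the event time
        jd = _julian_day(t)
        decl, eqtime = _sun_declination_eqtime(jd)
        cos_ha = (
            np.cos(np.deg2rad(_SUN_ZENITH_DEG)) / (np.cos(lat) * np.cos(decl))
            - np.tan(lat) * np.tan(decl)
        )
        cos_ha = min(1.0, max(-1.0, float(cos_ha)))
        ha = np.rad2deg(np.arccos(cos_ha))
        if not rise:
            ha = -ha
        minutes_utc = 720.0 - 4.0 * (longitude + ha) - eqtime
        out.append(
            dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
            + dt.timedelta(minutes=float(minutes_utc))
        )
        jd = _julian_day(noon_guess) - longitude / 360.0
    return out[0], out[1]


def moon_fraction(t) -> float | np.ndarray:
    """Illuminated fraction of the lunar disc in [0, 1].

    Truncated-series lunar/solar longitudes give the phase angle *i*; the
    fraction is ``(1 + cos i) / 2`` — 0 at new moon, 1 at full moon.
    Accepts a datetime or an array-like of datetimes.
    """
    ts = pd.to_datetime(t, utc=True)
    scalar = not isinstance(ts, (pd.DatetimeIndex, pd.Series))
    idx = pd.DatetimeIndex([ts]) if scalar else pd.DatetimeIndex(ts)
    jd = (
        idx.tz_convert("UTC").tz_localize(None).asi8 / 86_400_000_000_000.0
        + 2440587.5
    )
    tcent = (jd - 2451545.0) / 36525.0
    # mean elongation of the moon, sun mean anomaly, moon mean anomaly (deg)
    d = 297.8501921 + 445267.1114034 * tcent - 0.0018819 * tcent**2
    m = 357.5291092 + 35999.0502909 * tcent - 0.0001536 * tcent**2
    mp = 134.9633964 + 477198.8675055 * tcent + 0.0087414 * tcent**2
    d, m, mp = (np.deg2rad(x % 360.0) for x in (d, m, mp))
    phase_angle = np.deg2rad(180.0) - d - np.deg2rad(
        6.289 * np.sin(mp)
        - 2.100 * np.sin(m)
        - 1.274 * np.sin(2 * d - mp)
        - 0.658 * np.sin(2 * d)
        - 0.214 * np.sin(2 * mp)
        - 0.110 * np.sin(d)
    )
    frac = (1.0 + np.cos(phase_angle)) / 2.0
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac[0]) if scalar else frac


# Astronomical equinox/solstice dates (UTC calendar dates) bracketing a
# 2016-2020 window; used for season assignment.
SOLSTICE_EQUINOX_UTC: dict[int, tuple[dt.date, dt.date, dt.date, dt.date]] = {
    2016: (dt.date(2016, 3, 20), dt.date(2016, 6, 20), dt.date(2016, 9, 22), dt.date(2016, 12, 21)),
    2017: (dt.date(2017, 3, 20), dt.date(2017, 6, 21), dt.date(2017, 9, 22), dt.date(2017, 12, 21)),
    2018: (dt.date(2018, 3, 20), dt.date(2018, 6, 21), dt.date(2018, 9, 23), dt.date(2018, 12, 21)),
    2019: (dt.date(2019, 3, 20), dt.date(2019, 6, 21), dt.date(2019, 9, 23), dt.date(2019, 12, 22)),
    2020: (dt.date(2020, 3, 20), dt.date(2020, 6, 20), dt.date(2020, 9, 22), dt.date(2020, 12, 21)),
}


def season_boundaries(year: int) -> tuple[dt.date, dt.date, dt.date, dt.date]:
    """(vernal equinox, summer solstice, autumnal equinox, winter solstice)."""
    try:
        return SOLSTICE_EQUINOX_UTC[year]
    except KeyError:
        raise ValueError(
            f"no tabulated equinox/solstice dates for year {year}"
        ) from None
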