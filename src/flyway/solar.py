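"""Low-precision solar ephemeris (Meeus truncated series).

Solar declination and the equation of time are derived from the apparent
solar longitude (Meeus' low-accuracy solar position), good to about 0.01
degree over 1950-2100 — far inside the ~150 km working error of threshold
geolocation.  Elevations are geometric (no atmospheric refraction); the
calibrated sun elevation angle absorbs refraction together with sensor and
habitat shading.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_MIN_PER_DEG = 4.0  # Earth rotation: 4 minutes of time per degree of longitude
_JD_UNIX_EPOCH = 2440587.5


def _sun_apparent(times: pd.DatetimeIndex):
    """(declination deg, equation of time min) from the apparent solar
    longitude; truncated nutation/aberration terms included."""
    jd = times.asi8 / 86.4e12 + _JD_UNIX_EPOCH
    t = (jd - 2451545.0) / 36525.0
    mean_lon = (280.46646 + 36000.76983 * t + 0.0003032 * t * t) % 360.0
    anomaly = np.radians(357.52911 + 35999.05029 * t - 0.0001537 * t * t)
    center = (
        (1.914602 - 0.004817 * t - 0.000014 * t * t) * np.sin(anomaly)
        + (0.019993 - 0.000101 * t) * np.sin(2 * anomaly)
        + 0.000289 * np.sin(3 * anomaly)
    )
    omega = np.radians(125.04 - 1934.136 * t)
    app_lon = np.radians(mean_lon + center - 0.00569 - 0.00478 * np.sin(omega))
    obliquity = np.radians(
        23.4392911 - (46.8150 * t + 0.00059 * t * t) / 3600.0
        + 0.00256 * np.cos(omega)
    )
    decl = np.arcsin(np.sin(obliquity) * np.sin(app_lon))
    ra = np.degrees(np.arctan2(np.cos(obliquity) * np.sin(app_lon),
                               np.cos(app_lon))) % 360.0
    eq_deg = (mean_lon - 0.0057183 - ra + 180.0) % 360.0 - 180.0
    return np.degrees(decl), _MIN_PER_DEG * eq_deg


def equation_of_time_min(times) -> np.ndarray:
    """Equation of time in minutes (apparent minus mean solar time)."""
    return _sun_apparent(_as_index(times))[1]


def declination_deg(times) -> np.ndarray:
    """Solar declination in degrees."""
    return _sun_apparent(_as_index(times))[0]


def _as_index(times) -> pd.DatetimeIndex:
    if isinstance(times, pd.DatetimeIndex):
        idx = times
    elif isinstance(times, (list, tuple, np.ndarray, pd.Series)):
        idx = pd.DatetimeIndex(times)
    else:
        idx = pd.DatetimeIndex([pd.Timestamp(times)])
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    else:
        idx = idx.tz_convert("UTC")
    return idx


def solar_position(times, lat, lon):
    """Solar elevation and azimuth (degrees) at UTC time(s) and position(s).

    Parameters broadcast against each other; azimuth is measured clockwise
    from true north.  Returns ``(elevation, azimuth)`` as floats or arrays.
    """
    idx = _as_index(times)
    scalar = np.ndim(lat) == 0 and len(idx) == 1 and np.ndim(times) == 0
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    decl_deg, eqt = _sun_apparent(idx)
    decl = np.radians(decl_deg)
    utc_min = (
        idx.hour.to_numpy(dtype=float) * 60.0
        + idx.minute.to_numpy(dtype=float)
        + idx.second.to_numpy(dtype=float) / 60.0
        + idx.microsecond.to_numpy(dtype=float) / 6.0e7
    )
    tst = utc_min + eqt + _MIN_PER_DEG * lon  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle
    phi = np.radians(lat)
    cos_zen = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    zen = np.arccos(np.clip(cos_zen, -1.0, 1.0))
    elev = 90.0 - np.degrees(zen)
    az = np.degrees(
        np.arctan2(
            np.sin(ha),
            np.cos(ha) * np.sin(phi) - np.tan(decl) * np.cos(phi),
        )
    ) + 180.0
    az = az % 360.0
    if scalar:
        return float(elev[0]), float(az[0])
    return elev, az


def solar_elevation(times, lat, lon):
    return solar_position(times, lat, lon)[0]


def crossing_minutes_utc(dates, lat, lon, angle_deg, rising, n_iter: int = 2):
    """UTC minutes-of-day when solar elevation crosses ``angle_deg``.

    ``dates`` are the UTC civil dates (any times on those dates); ``rising``
    selects the morning (True) or evening (False) crossing.  NaN where the
    sun never reaches the angle that day (polar day/night).  Vectorised over
    all arguments; iterates the sunrise equation so the declination and
    equation of time are evaluated at the event itself.
    """
    idx = _as_index(dates)
    lat = np.broadcast_to(np.asarray(lat, dtype=float), idx.shape).astype(float)
    lon = np.broadcast_to(np.asarray(lon, dtype=float), idx.shape).astype(float)
    day0 = idx.normalize()
    # first guess: local noon
    est = day0 + pd.to_timedelta(720.0 - _MIN_PER_DEG * lon, unit="m")
    minutes = None
    for _ in range(n_iter):
        decl_deg, eqt = _sun_apparent(_as_index(est))
        decl = np.radians(decl_deg)
        phi = np.radians(lat)
        a = np.radians(angle_deg)
        cos_h0 = (np.sin(a) - np.sin(phi) * np.sin(decl)) / (
            np.cos(phi) * np.cos(decl)
        )
        with np.errstate(invalid="ignore"):
            h0 = np.degrees(np.arccos(np.where(np.abs(cos_h0) <= 1, cos_h0, np.nan)))
        noon = 720.0 - _MIN_PER_DEG * lon - eqt
        minutes = np.where(rising, noon - _MIN_PER_DEG * h0, noon + _MIN_PER_DEG * h0)
        est = day0 + pd.to_timedelta(np.nan_to_num(minutes, nan=720.0), unit="m")
    return minutes


def crossing_time(date, lat, lon, angle_deg, rising) -> pd.Timestamp | None:
    """Scalar convenience wrapper around :func:`crossing_minutes_utc`."""
    m = crossing_minutes_utc(pd.DatetimeIndex([pd.Timestamp(date)]), lat, lon,
                             angle_deg, rising)
    if np.isnan(m[0]):
        return None
    base = _as_index(pd.DatetimeIndex([pd.Timestamp(date)])).normalize()[0]
    return base + pd.Timedelta(minutes=float(m[0]))
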