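"""Environmental annotation: wind support, elevation profiles, inferred altitude.

Wind support for a flight leg is v_w * cos(alpha), the component of the wind
vector along the bird's track direction (positive = tailwind); scalar
airspeed is ground speed minus support.  Minimum route elevations are read
off a DEM in 0.1 degree latitude bins along the densified great-circle
route.  Flight altitude is inferred from geolocator cooling relative to the
pre-departure baseline at the standard tropospheric lapse rate of
6.5 degC per km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Track, gc_interpolate, haversine_km, initial_bearing_deg
from .synthetic import LEVELS, ElevationGrid, WindField

DEFAULT_LAPSE_C_PER_KM = 6.5


@dataclass
class WindSupportRecord:
    start_index: int
    end_index: int
    level: str  # 'surface' | 'mb850' | 'mb700' | 'max'
    wind_speed_kmh: float
    alpha_deg: float  # angle between track and wind direction
    support_kmh: float  # signed, v_w * cos(alpha)
    air_speed_kmh: float
    ground_speed_kmh: float
    missing: bool = False


def _leg_midpoint(track: Track, i: int):
    lats, lons = track.lats(), track.lons()
    mlat, mlon = gc_interpolate(lats[i], lons[i], lats[i + 1], lons[i + 1],
                                np.array([0.5]))
    times = track.times()
    tmid = times[i] + (times[i + 1] - times[i]) / 2
    return float(mlat[0]), float(mlon[0]), tmid


def wind_support(track: Track, i: int, wind_field: WindField,
                 level: str) -> WindSupportRecord:
    """Wind support and airspeed for the leg from fix i to fix i+1.

    The wind is sampled at the leg midpoint in space and time (bilinear in
    space, nearest in time); the track direction is the leg's initial
    great-circle bearing.  ``level='max'`` takes the pointwise maximum of
    the three signed supports.
    """
    lats, lons = track.lats(), track.lons()
    times = track.times()
    dt_h = (times[i + 1] - times[i]).total_seconds() / 3600.0
    dist = haversine_km(lats[i], lons[i], lats[i + 1], lons[i + 1])
    ground = dist / dt_h if dt_h > 0 else np.nan
    bearing = initial_bearing_deg(lats[i], lons[i], lats[i + 1], lons[i + 1])
    mlat, mlon, tmid = _leg_midpoint(track, i)

    def one_level(lev):
        u, v = wind_field.sample(lev, tmid, mlat, mlon)
        if not (np.isfinite(u) and np.isfinite(v)):
            return None
        vw = float(np.hypot(u, v))
        theta = np.radians(bearing)
        support = float(u * np.sin(theta) + v * np.cos(theta))
        wind_dir = np.degrees(np.arctan2(u, v)) % 360.0
        alpha = abs((wind_dir - bearing + 180.0) % 360.0 - 180.0)
        return vw, float(alpha), support

    if level == "max":
        best = None
        for lev in LEVELS:
            r = one_level(lev)
            if r is not None and (best is None or r[2] > best[2]):
                best = r
        result = best
    else:
        result = one_level(level)
    if result is None:
        return WindSupportRecord(i, i + 1, level, np.nan, np.nan, np.nan,
                                 np.nan, float(ground), missing=True)
    vw, alpha, support = result
    return WindSupportRecord(
        start_index=i, end_index=i + 1, level=level,
        wind_speed_kmh=vw, alpha_deg=alpha, support_kmh=support,
        air_speed_kmh=float(ground - support), ground_speed_kmh=float(ground),
    )


def annotate_wind(track: Track, wind_field: WindField,
                  levels: tuple[str, ...] = LEVELS + ("max",),
                  max_leg_hours: float = 24.0) -> pd.DataFrame:
    """One row per leg per level; legs longer than ``max_leg_hours`` skipped."""
    times = track.times()
    rows = []
    for i in range(len(track) - 1):
        dt_h = (times[i + 1] - times[i]).total_seconds() / 3600.0
        if dt_h <= 0 or dt_h > max_leg_hours:
            continue
        for lev in levels:
            rows.append(vars(wind_support(track, i, wind_field, lev)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Minimum elevation profiles
# ---------------------------------------------------------------------------


@dataclass
class ElevationProfile:
    bin_edges: np.ndarray  # ascending 0.1-degree latitude bin lower edges
    min_elevation: np.ndarray  # masl per bin, NaN where route exits the DEM
    mean_min_elevation: float  # per-individual mean over valid bins


def min_elevation_profile(track: Track, dem: ElevationGrid,
                          bin_deg: float = 0.1,
                          step_deg: float = 0.05) -> ElevationProfile:
    """Minimum route elevation per latitude bin.

    The route is densified along great circles at ``step_deg``, the DEM
    sampled bilinearly along it, and the minimum taken in each half-open
    ``[x, x + bin_deg)`` latitude bin; the per-individual summary is the
    unweighted mean of bin minima.
    """
    lats, lons = _densified(track, step_deg)
    elev = np.asarray(dem.sample(lats, lons), dtype=float)
    lo = np.floor(lats.min() / bin_deg) * bin_deg
    hi = np.floor(lats.max() / bin_deg) * bin_deg
    edges = np.round(np.arange(lo, hi + bin_deg / 2, bin_deg), 10)
    mins = np.full(len(edges), np.nan)
    which = np.floor((lats - lo) / bin_deg).astype(int)
    which = np.clip(which, 0, len(edges) - 1)
    for b in range(len(edges)):
        vals = elev[which == b]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            mins[b] = vals.min()
    valid = np.isfinite(mins)
    mean = float(np.mean(mins[valid])) if valid.any() else np.nan
    return ElevationProfile(bin_edges=edges, min_elevation=mins,
                            mean_min_elevation=mean)


def _densified(track: Track, step_deg: float):
    lats, lons = track.lats(), track.lons()
    out_lat, out_lon = [], []
    for i in range(len(track) - 1):
        d_deg = max(
            abs(lats[i + 1] - lats[i]),
            abs((lons[i + 1] - lons[i] + 180.0) % 360.0 - 180.0),
        )
        n = max(int(np.ceil(d_deg / step_deg)), 1)
        frac = np.linspace(0.0, 1.0, n + 1)[:-1]
        glat, glon = gc_interpolate(lats[i], lons[i], lats[i + 1],
                                    lons[i + 1], frac)
        out_lat.append(glat)
        out_lon.append(glon)
    out_lat.append(np.array([lats[-1]]))
    out_lon.append(np.array([lons[-1]]))
    return np.concatenate(out_lat), np.concatenate(out_lon)


# ---------------------------------------------------------------------------
# Altitude from geolocator temperature
# ---------------------------------------------------------------------------


@dataclass
class InferredAltitude:
    times: pd.DatetimeIndex  # post-departure 4-h block starts
    delta_t_c: np.ndarray  # baseline minus block temperature
    altitude_m: np.ndarray  # delta_t / lapse * 1000


def altitude_from_temperature(temperature: pd.Series,
                              departure_time: pd.Timestamp,
                              lapse_c_per_km: float = DEFAULT_LAPSE_C_PER_KM,
                              baseline_hours: float = 24.0
                              ) -> InferredAltitude:
    """Flight altitude inferred from tag cooling after departure.

    The baseline is the mean of the temperature blocks within
    ``baseline_hours`` before departure; each post-departure block's drop
    from that baseline converts to altitude at the given lapse rate
    (altitude is linear in the drop: delta_T / 6.5 km by default).
    """
    departure_time = pd.Timestamp(departure_time)
    if departure_time.tzinfo is None:
        departure_time = departure_time.tz_localize("UTC")
    idx = temperature.index
    pre = temperature[(idx < departure_time)
                      & (idx >= departure_time - pd.Timedelta(hours=baseline_hours))]
    if len(pre) == 0:
        raise ValueError("no pre-departure blocks: baseline unavailable")
    baseline = float(pre.mean())
    post = temperature[idx >= departure_time]
    delta = baseline - post.to_numpy(dtype=float)
    altitude = delta / lapse_c_per_km * 1000.0
    return InferredAltitude(times=post.index, delta_t_c=delta,
                            altitude_m=altitude)


def altitude_for_drop(delta_t_c: float,
                      lapse_c_per_km: float = DEFAULT_LAPSE_C_PER_KM) -> float:
    """Altitude (m) implied by a temperature drop at the given lapse rate."""
    return float(delta_t_c) / lapse_c_per_km * 1000.0
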