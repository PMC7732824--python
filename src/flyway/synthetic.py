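"""Seeded generators for ground-truth migrations and degraded sensor products.

A :class:`SimulationPlan` describes a multi-leg migration (wintering grounds
-> stopovers -> breeding grounds, optionally back) with residency durations,
a constant flight ground speed and altitude, the Argos duty cycle and the
twilight shading-noise model.  :func:`simulate_track` realises it as a truth
track at 1-h cadence, which the degraders turn into the sensor products a
real deployment yields: duty-cycled Argos fixes with class errors, a 5-min
light series with one-sided shading noise, 4-h temperature blocks following
a 6.5 degC/km lapse, and hourly immersion (wetness) counts capped at 14.

All randomness flows from the plan's seed (or an explicit seed argument), so
identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .core import (
    CLASS_ERROR_KM,
    GeoPosition,
    QualityClass,
    Track,
    TrackFix,
    destination,
    gc_interpolate,
    haversine_km,
    wrap_lon,
)

DEFAULT_LAPSE_C_PER_KM = 6.5

# ---------------------------------------------------------------------------
# Plans and phase schedules
# ---------------------------------------------------------------------------


@dataclass
class SimulationPlan:
    """Ground-truth migration scenario.

    waypoints: (lat, lon) sequence wintering -> stopovers -> breeding (a
    round trip simply lists the deployment site again at the end).
    stopover_durations_days: residency at each *interior* waypoint.
    initial/final_residency_days: time spent at the first/last waypoint
    (the deployment-site residencies that calibration and phase assignment
    rely on).
    """

    waypoints: list[tuple[float, float]]
    stopover_durations_days: list[float] = field(default_factory=list)
    flight_ground_speed_kmh: float = 55.0
    flight_altitude_masl: float = 4000.0
    duty_cycle_hours: tuple[float, float] = (10.0, 48.0)
    twilight_shading_gamma: tuple[float, float] = (2.0, 0.5)  # shape, rate (1/min)
    seed: int = 0
    start_time: pd.Timestamp = pd.Timestamp("2019-01-01T00:00:00Z")
    initial_residency_days: float = 20.0
    final_residency_days: float = 10.0
    stopover_jitter_km: float = 0.5
    light_threshold_elevation_deg: float = -3.5
    argos_class_mixture: dict = field(
        default_factory=lambda: {"G3": 0.4, "G2": 0.3, "G1": 0.3}
    )

    def __post_init__(self):
        if len(self.waypoints) < 2:
            raise ValueError("plan needs at least two waypoints")
        n_interior = len(self.waypoints) - 2
        if len(self.stopover_durations_days) != n_interior:
            raise ValueError(
                f"need {n_interior} stopover durations for "
                f"{len(self.waypoints)} waypoints"
            )
        if any(d < 0 for d in self.stopover_durations_days):
            raise ValueError("stopover durations must be >= 0")
        if self.flight_ground_speed_kmh <= 0:
            raise ValueError("flight ground speed must be > 0")
        for (a, b) in zip(self.waypoints[:-1], self.waypoints[1:]):
            if haversine_km(a[0], a[1], b[0], b[1]) < 1e-9:
                raise ValueError("consecutive waypoints must differ")
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.tz_localize("UTC")

    def schedule(self) -> list[dict]:
        """Deterministic phase schedule: residencies and flights in order.

        Each entry has kind ('residency'|'flight'), start, end, and the
        waypoint index (residency) or pair (flight).
        """
        phases = []
        t = self.start_time
        durations = (
            [self.initial_residency_days]
            + list(self.stopover_durations_days)
            + [self.final_residency_days]
        )
        for i, (wp, dur) in enumerate(zip(self.waypoints, durations)):
            if dur > 0:
                end = t + pd.Timedelta(days=float(dur))
                phases.append(
                    {"kind": "residency", "start": t, "end": end, "waypoint": i}
                )
                t = end
            if i < len(self.waypoints) - 1:
                a, b = self.waypoints[i], self.waypoints[i + 1]
                dist = haversine_km(a[0], a[1], b[0], b[1])
                end = t + pd.Timedelta(hours=dist / self.flight_ground_speed_kmh)
                phases.append(
                    {"kind": "flight", "start": t, "end": end, "waypoint": (i, i + 1)}
                )
                t = end
        return phases

    def total_great_circle_km(self) -> float:
        return float(
            sum(
                haversine_km(a[0], a[1], b[0], b[1])
                for a, b in zip(self.waypoints[:-1], self.waypoints[1:])
            )
        )


# ---------------------------------------------------------------------------
# Truth track
# ---------------------------------------------------------------------------


def simulate_track(plan: SimulationPlan, cadence_hours: float = 1.0) -> Track:
    """Realise the plan as a TRUTH track at fixed cadence.

    Residency positions jitter isotropically within ``plan.stopover_jitter_km``
    of the waypoint; flight positions follow the great-circle leg at the
    plan's ground speed.  Flight fixes carry ``altitude_true`` equal to the
    plan's flight altitude, residencies sit at sea level.
    """
    rng = np.random.default_rng(plan.seed)
    phases = plan.schedule()
    t_end = phases[-1]["end"]
    times = pd.date_range(plan.start_time, t_end, freq=pd.Timedelta(hours=cadence_hours))
    lats = np.empty(len(times))
    lons = np.empty(len(times))
    alts = np.zeros(len(times))
    tvals = times.asi8
    for ph in phases:
        mask = (tvals >= ph["start"].value) & (tvals <= ph["end"].value)
        n = int(mask.sum())
        if n == 0:
            continue
        if ph["kind"] == "residency":
            wlat, wlon = plan.waypoints[ph["waypoint"]]
            r = plan.stopover_jitter_km * np.sqrt(rng.uniform(size=n))
            theta = rng.uniform(0, 360, size=n)
            jlat, jlon = destination(wlat, wlon, theta, r)
            lats[mask] = jlat
            lons[mask] = jlon
            alts[mask] = 0.0
        else:
            i, j = ph["waypoint"]
            a, b = plan.waypoints[i], plan.waypoints[j]
            span = (ph["end"] - ph["start"]).total_seconds()
            frac = (tvals[mask] - ph["start"].value) / 1e9 / span
            glat, glon = gc_interpolate(a[0], a[1], b[0], b[1], frac)
            lats[mask] = glat
            lons[mask] = glon
            alts[mask] = plan.flight_altitude_masl
    fixes = [
        TrackFix(
            position=GeoPosition(float(la), float(lo), t),
            error_radius=0.0,
            quality_class=QualityClass.TRUTH,
            altitude_true=float(al),
        )
        for la, lo, t, al in zip(lats, lons, times, alts)
    ]
    return Track(bird_id=f"sim-{plan.seed}", species="other",
                 tag_type="ptt", fixes=fixes)


def phase_at(plan: SimulationPlan, times: pd.DatetimeIndex) -> np.ndarray:
    """Phase kind ('residency'|'flight') per timestamp, from the plan schedule."""
    out = np.full(len(times), "residency", dtype=object)
    tv = times.asi8
    for ph in plan.schedule():
        if ph["kind"] == "flight":
            mask = (tv > ph["start"].value) & (tv < ph["end"].value)
            out[mask] = "flight"
    return out


# ---------------------------------------------------------------------------
# Argos degradation
# ---------------------------------------------------------------------------


def degrade_to_argos(track: Track, plan: SimulationPlan,
                     seed: int | None = None) -> Track:
    """Duty-cycle and noise a truth track into Argos-style fixes.

    Keeps only fixes inside 'on' windows of the (hours_on, hours_off) duty
    cycle anchored at the plan's start time (tag activation); each retained
    fix gets a quality class
    drawn from the plan's mixture and an isotropic displacement drawn
    uniformly within that class's nominal error radius, so class bounds are
    never exceeded.
    """
    rng = np.random.default_rng(plan.seed + 1 if seed is None else seed)
    on, off = plan.duty_cycle_hours
    period = on + off
    times = track.times()
    hours = (times.asi8 - plan.start_time.value) / 3.6e12
    in_window = (hours % period) < on
    idx = np.nonzero(in_window)[0]
    if len(idx) == 0:
        warnings.warn("duty cycle leaves no on-window fixes; empty track")
        return Track(bird_id=track.bird_id, species=track.species,
                     tag_type="ptt", fixes=[], validate=False)
    classes = list(plan.argos_class_mixture.keys())
    probs = np.array(list(plan.argos_class_mixture.values()), dtype=float)
    probs /= probs.sum()
    drawn = rng.choice(len(classes), size=len(idx), p=probs)
    fixes = []
    for k, i in enumerate(idx):
        qc = QualityClass(classes[drawn[k]])
        radius = CLASS_ERROR_KM[qc]
        r = radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 360)
        f = track.fixes[i]
        nlat, nlon = destination(f.position.lat, f.position.lon, theta, r)
        fixes.append(
            TrackFix(
                position=GeoPosition(float(nlat), float(nlon), f.position.time),
                error_radius=radius,
                quality_class=qc,
                altitude_true=f.altitude_true,
            )
        )
    return Track(bird_id=track.bird_id, species=track.species,
                 tag_type="ptt", fixes=fixes, validate=False)


# ---------------------------------------------------------------------------
# Geolocator stream
# ---------------------------------------------------------------------------


@dataclass
class GeolocatorStream:
    """Co-registered light / temperature / wetness series from one tag."""

    light: pd.Series  # 5-min cadence, raw sensor units
    temperature: pd.Series  # 4-h block starts, degC
    wetness: pd.Series  # hour starts, counts 0..14


# Light response: logistic in solar elevation with a dark floor.  Only the
# threshold-crossing time matters downstream, so the radiometric scale is
# arbitrary; the curve is anchored so log(light) = 1 exactly at the plan's
# threshold elevation.
_LIGHT_MAX = 64.0
_LIGHT_FLOOR = 0.3
_LIGHT_STEEPNESS = 1.2  # per degree of solar elevation


def _light_from_elevation(elev_deg, threshold_elev_deg):
    target = (np.e - _LIGHT_FLOOR) / (_LIGHT_MAX - _LIGHT_FLOOR)
    half = threshold_elev_deg + np.log(1.0 / target - 1.0) / _LIGHT_STEEPNESS
    return _LIGHT_FLOOR + (_LIGHT_MAX - _LIGHT_FLOOR) / (
        1.0 + np.exp(-_LIGHT_STEEPNESS * (np.asarray(elev_deg) - half))
    )


def _positions_at(track: Track, times: pd.DatetimeIndex):
    """Linear (in time) interpolation of track positions onto ``times``."""
    tt = track.times().asi8
    lat = np.interp(times.asi8, tt, track.lats())
    # unwrap longitudes before interpolating across the dateline
    lon_unwrapped = np.degrees(np.unwrap(np.radians(track.lons())))
    lon = wrap_lon(np.interp(times.asi8, tt, lon_unwrapped))
    return lat, lon


def simulate_light(track: Track, plan: SimulationPlan,
                   seed: int | None = None) -> pd.Series:
    """5-min raw light series along the truth track with shading noise.

    Shading can only remove light, so the per-day gamma-distributed errors
    act one-sided: dawn is delayed and dusk advanced by independent draws
    from the plan's shading distribution (minutes).
    """
    rng = np.random.default_rng(plan.seed + 2 if seed is None else seed)
    times = pd.date_range(track.fixes[0].position.time,
                          track.fixes[-1].position.time, freq="5min")
    lat, lon = _positions_at(track, times)
    shape, rate = plan.twilight_shading_gamma
    # local solar day index for one draw per dawn/dusk per day
    local_day = ((times.asi8 / 3.6e12 + lon / 15.0) // 24.0).astype(int)
    day_codes, day_idx = np.unique(local_day, return_inverse=True)
    if shape > 0 and rate > 0:
        dawn_delay = rng.gamma(shape, 1.0 / rate, size=len(day_codes))
        dusk_advance = rng.gamma(shape, 1.0 / rate, size=len(day_codes))
    else:
        dawn_delay = np.zeros(len(day_codes))
        dusk_advance = np.zeros(len(day_codes))
    # morning samples (hour angle < 0) are evaluated at t - delay so the
    # threshold crossing happens `delay` minutes late; evening samples at
    # t + advance so dusk crosses early.
    eqt = solar.equation_of_time_min(times)
    tst = (times.hour * 60 + times.minute + times.second / 60.0).to_numpy() \
        + eqt + 4.0 * lon
    ha = (tst / 4.0 - 180.0 + 180.0) % 360.0 - 180.0
    is_morning = ha < 0
    shift_min = np.where(is_morning, -dawn_delay[day_idx], dusk_advance[day_idx])
    shifted = times + pd.to_timedelta(shift_min, unit="m")
    elev, _ = solar.solar_position(pd.DatetimeIndex(shifted), lat, lon)
    light = _light_from_elevation(elev, plan.light_threshold_elevation_deg)
    return pd.Series(light, index=times, name="light")


def simulate_temperature(track: Track, plan: SimulationPlan,
                         seed: int | None = None,
                         noise_sd_c: float = 0.8,
                         lapse_c_per_km: float = DEFAULT_LAPSE_C_PER_KM) -> pd.Series:
    """4-h block temperatures: surface climatology minus the lapse-rate term.

    Surface climatology is a simple latitude ramp (30 degC at the equator,
    falling 0.35 degC per degree of latitude); flight altitude cools the tag
    at ``lapse_c_per_km``.
    """
    rng = np.random.default_rng(plan.seed + 3 if seed is None else seed)
    start = track.fixes[0].position.time.floor("4h")
    blocks = pd.date_range(start, track.fixes[-1].position.time, freq="4h")
    # sample hourly within each block and average
    temps = np.empty(len(blocks))
    alts = np.array([
        0.0 if f.altitude_true is None else f.altitude_true for f in track.fixes
    ])
    if any(f.altitude_true is None for f in track.fixes):
        warnings.warn("missing altitude_true treated as 0 masl")
    tt = track.times().asi8
    for i, b in enumerate(blocks):
        sub = pd.date_range(b, b + pd.Timedelta(hours=4), freq="1h")[:-1]
        lat = np.interp(sub.asi8, tt, track.lats())
        alt = np.interp(sub.asi8, tt, alts)
        surface = 30.0 - 0.35 * np.abs(lat)
        temps[i] = np.mean(surface - lapse_c_per_km * alt / 1000.0)
    temps += rng.normal(0.0, noise_sd_c, size=len(blocks))
    return pd.Series(temps, index=blocks, name="temperature")


def simulate_wetness(track: Track, plan: SimulationPlan,
                     seed: int | None = None,
                     immersion_probability: float = 0.5,
                     wet_cap: int = 14,
                     coastal_max_masl: float = 10.0) -> pd.Series:
    """Hourly wetness counts: immersion only while stationary at the coast.

    Counts are binomial over the (up to) ``wet_cap`` conductivity samples per
    hour; flight hours are always dry, so wetness and flight are mutually
    exclusive by construction.
    """
    rng = np.random.default_rng(plan.seed + 4 if seed is None else seed)
    hours = pd.date_range(track.fixes[0].position.time.floor("1h"),
                          track.fixes[-1].position.time, freq="1h")
    kinds = phase_at(plan, hours)
    tt = track.times().asi8
    alts = np.array([
        0.0 if f.altitude_true is None else f.altitude_true for f in track.fixes
    ])
    alt = np.interp(hours.asi8, tt, alts)
    eligible = (kinds == "residency") & (alt <= coastal_max_masl)
    counts = np.zeros(len(hours), dtype=int)
    n_eligible = int(eligible.sum())
    if n_eligible:
        counts[eligible] = rng.binomial(wet_cap, immersion_probability,
                                        size=n_eligible)
    return pd.Series(counts, index=hours, name="wetness")


def simulate_stream(track: Track, plan: SimulationPlan) -> GeolocatorStream:
    """Convenience bundle of the three geolocator products."""
    return GeolocatorStream(
        light=simulate_light(track, plan),
        temperature=simulate_temperature(track, plan),
        wetness=simulate_wetness(track, plan),
    )


# ---------------------------------------------------------------------------
# Elevation grid and wind fields
# ---------------------------------------------------------------------------


@dataclass
class ElevationGrid:
    """Regular lat/lon elevation grid (masl), cell-centre registered."""

    lat_centers: np.ndarray  # ascending
    lon_centers: np.ndarray  # ascending
    elevation: np.ndarray  # (nlat, nlon)

    def __post_init__(self):
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        self.lon_centers = np.asarray(self.lon_centers, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.shape != (len(self.lat_centers), len(self.lon_centers)):
            raise ValueError("elevation shape mismatch")
        if not (np.all(np.diff(self.lat_centers) > 0)
                and np.all(np.diff(self.lon_centers) > 0)):
            raise ValueError("grid axes must be strictly ascending")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("elevations must be finite")

    @property
    def cellsize(self) -> float:
        return float(np.diff(self.lat_centers).mean())

    def sample(self, lat, lon):
        """Bilinear elevation at point(s); NaN outside the grid."""
        return _bilinear(self.lat_centers, self.lon_centers, self.elevation,
                         lat, lon)


def _bilinear(yc, xc, grid, lat, lon):
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    out = np.full(lat.shape, np.nan)
    inside = (
        (lat >= yc[0]) & (lat <= yc[-1]) & (lon >= xc[0]) & (lon <= xc[-1])
    )
    if inside.any():
        la, lo = lat[inside], lon[inside]
        iy = np.clip(np.searchsorted(yc, la) - 1, 0, len(yc) - 2)
        ix = np.clip(np.searchsorted(xc, lo) - 1, 0, len(xc) - 2)
        fy = (la - yc[iy]) / (yc[iy + 1] - yc[iy])
        fx = (lo - xc[ix]) / (xc[ix + 1] - xc[ix])
        v = (
            grid[iy, ix] * (1 - fy) * (1 - fx)
            + grid[iy + 1, ix] * fy * (1 - fx)
            + grid[iy, ix + 1] * (1 - fy) * fx
            + grid[iy + 1, ix + 1] * fy * fx
        )
        out[inside] = v
    return out if out.size > 1 else float(out[0])


@dataclass
class RidgeSpec:
    """Synthetic Himalaya-like east-west barrier for the elevation grid."""

    lat_min: float = 0.0
    lat_max: float = 45.0
    lon_min: float = 70.0
    lon_max: float = 110.0
    resolution_deg: float = 0.1
    crest_masl: float = 5500.0
    ridge_lat_band: tuple[float, float] = (27.0, 30.0)
    ridge_lon_band: tuple[float, float] = (75.0, 97.0)
    plateau_masl: float = 3500.0  # north of the ridge
    lowland_masl: float = 100.0
    passes: list[tuple[float, float, float]] = field(default_factory=list)
    # each pass: (longitude, floor elevation masl, half-width in degrees)


def make_dem(spec: RidgeSpec = RidgeSpec()) -> ElevationGrid:
    """Build the synthetic barrier DEM: tropical lowland, an east-west ridge
    with a Gaussian crest profile, a plateau to the north, and optional low
    passes notched into the crest at stated longitudes."""
    if spec.resolution_deg <= 0:
        raise ValueError("resolution must be > 0")
    lats = np.arange(spec.lat_min, spec.lat_max + spec.resolution_deg / 2,
                     spec.resolution_deg)
    lons = np.arange(spec.lon_min, spec.lon_max + spec.resolution_deg / 2,
                     spec.resolution_deg)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    lat0, lat1 = spec.ridge_lat_band
    lon0, lon1 = spec.ridge_lon_band
    ridge_center = 0.5 * (lat0 + lat1)
    ridge_sigma = (lat1 - lat0) / 3.0
    elev = np.full(glat.shape, spec.lowland_masl)
    # plateau north of the ridge band, within the ridge longitudes, with
    # cosine-tapered edges so the terrain is smooth at sub-cell scale
    ramp_n = np.clip((lat1 + 12.0 - glat) / 2.0, 0.0, 1.0)
    ramp_s = np.clip((glat - lat1) / 1.0, 0.0, 1.0)
    taper = 0.5 * (1 - np.cos(np.pi * ramp_n)) * 0.5 * (1 - np.cos(np.pi * ramp_s))
    plateau = (glon >= lon0) & (glon <= lon1)
    elev = np.where(
        plateau,
        np.maximum(elev, spec.lowland_masl
                   + (spec.plateau_masl - spec.lowland_masl) * taper),
        elev,
    )
    in_ridge = (glat >= lat0 - 2) & (glat <= lat1 + 2) & \
        (glon >= lon0) & (glon <= lon1)
    crest = spec.crest_masl * np.exp(
        -0.5 * ((glat - ridge_center) / ridge_sigma) ** 2
    )
    elev = np.where(in_ridge, np.maximum(elev, crest), elev)
    for pass_lon, pass_floor, half_width in spec.passes:
        notch = np.exp(-0.5 * ((glon - pass_lon) / half_width) ** 2)
        lowered = elev - (elev - pass_floor) * notch
        in_band = (glat >= lat0 - 2) & (glat <= lat1 + 2)
        elev = np.where(in_band & (elev > pass_floor),
                        np.maximum(lowered, pass_floor), elev)
    return ElevationGrid(lats, lons, elev)


@dataclass
class WindLevelSpec:
    """Mean wind vector plus smooth seeded perturbation for one level."""

    mean_u_kmh: float = 0.0
    mean_v_kmh: float = 0.0
    perturbation_kmh: float = 0.0  # amplitude of smooth spatial variation


@dataclass
class WindFieldSpec:
    lat_min: float = -10.0
    lat_max: float = 75.0
    lon_min: float = 60.0
    lon_max: float = 130.0
    resolution_deg: float = 1.0
    time_start: pd.Timestamp = pd.Timestamp("2019-01-01T00:00:00Z")
    time_end: pd.Timestamp = pd.Timestamp("2020-01-01T00:00:00Z")
    time_step_hours: float = 24.0
    levels: dict = field(
        default_factory=lambda: {
            "surface": WindLevelSpec(),
            "mb850": WindLevelSpec(),
            "mb700": WindLevelSpec(),
        }
    )


LEVELS = ("surface", "mb850", "mb700")


@dataclass
class WindField:
    """Gridded (u, v) wind components (km/h) on (time, lat, lon) per level."""

    times: pd.DatetimeIndex
    lat_centers: np.ndarray
    lon_centers: np.ndarray
    u: dict  # level -> (ntime, nlat, nlon)
    v: dict

    def __post_init__(self):
        for lev in LEVELS:
            if lev not in self.u or lev not in self.v:
                raise ValueError(f"missing wind level {lev}")
            if not (np.all(np.isfinite(self.u[lev]))
                    and np.all(np.isfinite(self.v[lev]))):
                raise ValueError("wind components must be finite")

    def sample(self, level: str, time, lat, lon) -> tuple[float, float]:
        """(u, v) at a point: bilinear in space, nearest in time."""
        t = pd.Timestamp(time)
        if t.tzinfo is None:
            t = t.tz_localize("UTC")
        it = int(np.argmin(np.abs(self.times.asi8 - t.value)))
        u = _bilinear(self.lat_centers, self.lon_centers, self.u[level][it],
                      lat, lon)
        v = _bilinear(self.lat_centers, self.lon_centers, self.v[level][it],
                      lat, lon)
        return u, v


def make_wind_field(spec: WindFieldSpec = WindFieldSpec(), seed: int = 0) -> WindField:
    """Smooth seeded wind layers: per-level mean vector plus low-frequency
    sinusoidal perturbations in space and time."""
    if spec.resolution_deg <= 0:
        raise ValueError("resolution must be > 0")
    rng = np.random.default_rng(seed)
    lats = np.arange(spec.lat_min, spec.lat_max + spec.resolution_deg / 2,
                     spec.resolution_deg)
    lons = np.arange(spec.lon_min, spec.lon_max + spec.resolution_deg / 2,
                     spec.resolution_deg)
    times = pd.date_range(pd.Timestamp(spec.time_start),
                          pd.Timestamp(spec.time_end),
                          freq=pd.Timedelta(hours=spec.time_step_hours))
    if times.tz is None:
        times = times.tz_localize("UTC")
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    tdays = (times.asi8 - times.asi8[0]) / 86.4e12
    u, v = {}, {}
    for lev in LEVELS:
        lspec = spec.levels.get(lev, WindLevelSpec())
        phases = rng.uniform(0, 2 * np.pi, size=6)
        uu = np.empty((len(times), len(lats), len(lons)))
        vv = np.empty_like(uu)
        for k, td in enumerate(tdays):
            wobble_u = (
                np.sin(2 * np.pi * glat / 40.0 + phases[0] + 0.2 * td)
                + np.sin(2 * np.pi * glon / 60.0 + phases[1])
            ) / 2.0
            wobble_v = (
                np.sin(2 * np.pi * glat / 35.0 + phases[2] + 0.15 * td)
                + np.sin(2 * np.pi * glon / 50.0 + phases[3])
            ) / 2.0
            uu[k] = lspec.mean_u_kmh + lspec.perturbation_kmh * wobble_u
            vv[k] = lspec.mean_v_kmh + lspec.perturbation_kmh * wobble_v
        u[lev] = uu
        v[lev] = vv
    return WindField(times=times, lat_centers=lats, lon_centers=lons, u=u, v=v)
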