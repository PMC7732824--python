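"""Rule-based segmentation of located tracks.

Stopovers follow the operational field definition: a maximal run of fixes
within 150 km of its running centroid, lasting at least 3 days, flanked by
directional movements larger than the radius.  Terminal residencies (the
deployment-site and destination clusters) are reported separately as
residencies, not stopovers.  Departure instants can also be read from the
immersion (wetness) sensor: the end of the last wet hour before a sustained
dry run.  Seasonal phases and mountain-barrier crossings are derived on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GeoPosition,
    Track,
    centroid_latlon,
    gc_interpolate,
    haversine_km,
    sgt_date,
)
from .synthetic import ElevationGrid


@dataclass
class Stopover:
    centroid: GeoPosition
    arrival: pd.Timestamp
    departure: pd.Timestamp
    member_indices: list[int] = field(default_factory=list)
    is_terminal: bool = False  # deployment / destination residency

    @property
    def duration_days(self) -> float:
        return (self.departure - self.arrival).total_seconds() / 86400.0


@dataclass
class SegmentationResult:
    stopovers: list[Stopover]
    residencies: list[Stopover]  # terminal clusters (non-breeding / breeding)


def _cluster_fixes(track: Track, radius_km: float) -> list[list[int]]:
    """Greedy running-centroid clustering of consecutive fixes."""
    lats, lons = track.lats(), track.lons()
    clusters: list[list[int]] = []
    current = [0]
    clat, clon = lats[0], lons[0]
    for i in range(1, len(track)):
        if haversine_km(lats[i], lons[i], clat, clon) <= radius_km:
            current.append(i)
            clat, clon = centroid_latlon(lats[current], lons[current])
        else:
            clusters.append(current)
            current = [i]
            clat, clon = lats[i], lons[i]
    clusters.append(current)
    return clusters


def _travel_speed(track: Track, fallback_kmh: float = 55.0) -> float:
    """Median apparent flight speed over short legs (>= 20 km/h)."""
    times = track.times()
    lats, lons = track.lats(), track.lons()
    speeds = []
    for i in range(len(track) - 1):
        dt_h = (times[i + 1] - times[i]).total_seconds() / 3600.0
        if 0 < dt_h <= 24.0:
            v = haversine_km(lats[i], lons[i], lats[i + 1], lons[i + 1]) / dt_h
            if v >= 20.0:
                speeds.append(v)
    return float(np.median(speeds)) if speeds else fallback_kmh


def detect_stopovers(track: Track, radius_km: float = 150.0,
                     min_days: float = 3.0,
                     travel_speed_kmh: float | None = None
                     ) -> SegmentationResult:
    """Stopovers: >= min_days within radius_km, flanked by > radius_km moves.

    Duty-cycled tags truncate the observed fix span of a residency, so the
    arrival and departure instants are back-projected into the flanking
    transmission gaps at the bird's travel speed: arrival = time of the last
    distant fix plus its distance to the site centroid over the travel
    speed (clamped into the gap), and symmetrically for departure.  The
    >= min_days rule is applied to this credited duration, which keeps
    2-day pauses below a 3-day threshold while recovering stopovers whose
    fixes fall in few 'on' windows.  Clusters containing the first or last
    fix are the deployment and destination residencies and are reported
    separately, not as stopovers.
    """
    times = track.times()
    lats, lons = track.lats(), track.lons()
    if travel_speed_kmh is None:
        travel_speed_kmh = _travel_speed(track)
    clusters = _cluster_fixes(track, radius_km)
    stopovers: list[Stopover] = []
    residencies: list[Stopover] = []
    last_fix = len(track) - 1
    for members in clusters:
        clat, clon = centroid_latlon(lats[members], lons[members])
        i0, i1 = members[0], members[-1]
        arrival = times[i0]
        departure = times[i1]
        if i0 > 0:
            prev = i0 - 1
            lead_h = haversine_km(lats[prev], lons[prev], clat, clon) \
                / travel_speed_kmh
            est = times[prev] + pd.Timedelta(hours=lead_h)
            arrival = min(max(est, times[prev]), times[i0])
        if i1 < last_fix:
            nxt = i1 + 1
            lead_h = haversine_km(lats[nxt], lons[nxt], clat, clon) \
                / travel_speed_kmh
            est = times[nxt] - pd.Timedelta(hours=lead_h)
            departure = max(min(est, times[nxt]), times[i1])
        duration = (departure - arrival).total_seconds() / 86400.0
        if duration < min_days:
            continue
        # deployment / destination clusters are residencies, not stopovers;
        # interior clusters are flanked by > radius_km displacements by
        # construction (the cluster only closes when a fix leaves the
        # running-centroid radius)
        terminal = (0 in members) or (last_fix in members)
        s = Stopover(
            centroid=GeoPosition(clat, clon, arrival),
            arrival=arrival,
            departure=departure,
            member_indices=list(members),
            is_terminal=terminal,
        )
        (residencies if terminal else stopovers).append(s)
    return SegmentationResult(stopovers=stopovers, residencies=residencies)


# ---------------------------------------------------------------------------
# Departure from the immersion sensor
# ---------------------------------------------------------------------------


def detect_departure_from_wetness(wetness: pd.Series,
                                  min_dry_hours: int = 12
                                  ) -> pd.Timestamp | None:
    """Departure = end of the last wet hour before a sustained dry run.

    ``wetness`` is an hourly series of counts; a dry run must last at least
    ``min_dry_hours``.  Returns None when no such run follows a wet hour.
    """
    counts = wetness.to_numpy()
    idx = wetness.index
    wet = counts > 0
    if not wet.any():
        return None
    n = len(counts)
    i = 0
    candidate = None
    while i < n:
        if not wet[i]:
            j = i
            while j < n and not wet[j]:
                j += 1
            run_len = j - i
            if run_len >= min_dry_hours and i > 0 and wet[:i].any():
                last_wet = np.nonzero(wet[:i])[0][-1]
                candidate = idx[last_wet] + pd.Timedelta(hours=1)
                return candidate
            i = j
        else:
            i += 1
    return candidate


# ---------------------------------------------------------------------------
# Seasonal phases
# ---------------------------------------------------------------------------


@dataclass
class MigrationPhase:
    kind: str  # 'nonbreeding' | 'northward' | 'breeding' | 'southward'
    start: pd.Timestamp
    end: pd.Timestamp


@dataclass
class PhaseAssignment:
    phases: list[MigrationPhase]
    partial_migration: bool = False
    breeding_residency: Stopover | None = None
    nonbreeding_residency: Stopover | None = None


def assign_phases(track: Track, segmentation: SegmentationResult,
                  breeding_latitude: float = 30.0) -> PhaseAssignment:
    """Assign nonbreeding / northward / breeding / southward phases.

    The residency containing the first fix is the non-breeding residency;
    the northernmost residency at or above ``breeding_latitude`` is the
    breeding residency.  A track with no residency reaching the breeding
    latitude is flagged as a partial migration (sub-adult behaviour) and
    gets no breeding or southward phase.
    """
    residencies = sorted(segmentation.residencies + segmentation.stopovers,
                         key=lambda s: s.arrival)
    if not residencies:
        return PhaseAssignment(phases=[], partial_migration=True)
    nonbreeding = residencies[0]
    candidates = [s for s in residencies
                  if s.centroid.lat >= breeding_latitude]
    if not candidates:
        return PhaseAssignment(
            phases=[MigrationPhase("nonbreeding", nonbreeding.arrival,
                                   nonbreeding.departure)],
            partial_migration=True,
            nonbreeding_residency=nonbreeding,
        )
    breeding = max(candidates, key=lambda s: s.centroid.lat)
    phases = [
        MigrationPhase("nonbreeding", nonbreeding.arrival,
                       nonbreeding.departure),
        MigrationPhase("northward", nonbreeding.departure, breeding.arrival),
        MigrationPhase("breeding", breeding.arrival, breeding.departure),
    ]
    track_end = track.times()[-1]
    if track_end > breeding.departure:
        phases.append(
            MigrationPhase("southward", breeding.departure, track_end)
        )
    return PhaseAssignment(phases=phases, partial_migration=False,
                           breeding_residency=breeding,
                           nonbreeding_residency=nonbreeding)


# ---------------------------------------------------------------------------
# Barrier crossings
# ---------------------------------------------------------------------------


@dataclass
class BarrierCrossing:
    direction: str  # 'north' | 'south'
    lon_interval: tuple[float, float]
    date_interval: tuple[object, object]  # SGT dates
    entry_time: pd.Timestamp | None = None
    exit_time: pd.Timestamp | None = None


def detect_barrier_crossing(track: Track, dem: ElevationGrid,
                            crest_elevation: float = 4000.0,
                            step_deg: float = 0.05) -> list[BarrierCrossing]:
    """Passages of the track over the contiguous high-elevation mask.

    The track is densified along great circles (step <= ``step_deg``), the
    DEM sampled along it, and each contiguous run of samples at or above
    ``crest_elevation`` reported with its entry/exit longitudes and SGT
    dates.  Routes that never intersect the mask return an empty list.
    """
    lats, lons, tvals = _densify(track, step_deg)
    elev = dem.sample(lats, lons)
    above = np.asarray(elev) >= crest_elevation
    above = np.where(np.isnan(elev), False, above)
    crossings: list[BarrierCrossing] = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        t_in = pd.Timestamp(tvals[i], tz="UTC")
        t_out = pd.Timestamp(tvals[j], tz="UTC")
        direction = "north" if lats[j] >= lats[i] else "south"
        lo, hi = sorted((float(lons[i]), float(lons[j])))
        crossings.append(
            BarrierCrossing(
                direction=direction,
                lon_interval=(lo, hi),
                date_interval=(sgt_date(t_in), sgt_date(t_out)),
                entry_time=t_in,
                exit_time=t_out,
            )
        )
        i = j + 1
    return crossings


def _densify(track: Track, step_deg: float):
    """Great-circle densification with linear time interpolation."""
    lats, lons = track.lats(), track.lons()
    times = track.times().asi8
    out_lat, out_lon, out_t = [], [], []
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
        out_t.append(times[i] + frac * (times[i + 1] - times[i]))
    out_lat.append(np.array([lats[-1]]))
    out_lon.append(np.array([lons[-1]]))
    out_t.append(np.array([times[-1]], dtype=float))
    return (np.concatenate(out_lat), np.concatenate(out_lon),
            np.concatenate(out_t).astype("int64").view("datetime64[ns]"))
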