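"""Migration metrics: distances, detours, ground speeds and timing tables.

Distances are great-circle on a sphere of radius 6371 km (minimum flight
distances through consecutive locations and stopover centroids).  Apparent
ground speeds below 20 km/h are excluded because the 10 h on / 48 h off duty
cycle can hide short stopovers inside a leg.  Reported dates and whole-day
durations use the Singapore Time (UTC+8) calendar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeoPosition, Track, haversine_km, sgt_date
from .segmentation import PhaseAssignment, SegmentationResult, Stopover

MIN_RETAINED_SPEED_KMH = 20.0
MAX_SPEED_LEG_HOURS = 24.0


def great_circle_km(a: GeoPosition, b: GeoPosition) -> float:
    """Great-circle distance between two positions (km, spherical Earth)."""
    return haversine_km(a.lat, a.lon, b.lat, b.lon)


def _phase_indices(track: Track, start: pd.Timestamp,
                   end: pd.Timestamp) -> np.ndarray:
    """Fix indices spanning a phase, including the bracketing fixes.

    Phase boundaries (arrival/departure instants) are back-projected into
    transmission gaps, so the fixes just outside them — typically the last
    fix at the origin residency and the first at the destination — belong
    to the phase's route.
    """
    t = track.times()
    i0 = int(np.searchsorted(t, start, side="right")) - 1
    i1 = int(np.searchsorted(t, end, side="left"))
    i0 = max(i0, 0)
    i1 = min(i1, len(t) - 1)
    return np.arange(i0, i1 + 1)


def migration_distance(track: Track, segmentation: SegmentationResult,
                       start: pd.Timestamp, end: pd.Timestamp) -> float:
    """Minimum flight distance within a phase (km).

    Sums great-circle legs through the phase's fixes, with every stopover
    collapsed onto its centroid so within-site scatter does not inflate the
    total.
    """
    idx = _phase_indices(track, start, end)
    if len(idx) < 2:
        return 0.0
    clusters = {}
    for s in segmentation.stopovers + segmentation.residencies:
        for i in s.member_indices:
            clusters[i] = s
    lats, lons = track.lats(), track.lons()
    points: list[tuple[float, float]] = []
    last_cluster: Stopover | None = object()  # sentinel
    for i in idx:
        s = clusters.get(int(i))
        if s is None:
            points.append((lats[i], lons[i]))
            last_cluster = None
        elif s is not last_cluster:
            points.append((s.centroid.lat, s.centroid.lon))
            last_cluster = s
    total = 0.0
    for (la1, lo1), (la2, lo2) in zip(points[:-1], points[1:]):
        total += haversine_km(la1, lo1, la2, lo2)
    return float(total)


def detour_km(track: Track, segmentation: SegmentationResult,
              phases: PhaseAssignment, direction: str = "northward") -> float:
    """Extra track length above the straight line between the non-breeding
    and breeding residency centroids (km)."""
    if phases.breeding_residency is None or phases.nonbreeding_residency is None:
        raise ValueError("both endpoint residencies are required for a detour")
    phase = next(p for p in phases.phases if p.kind == direction)
    dist = migration_distance(track, segmentation, phase.start, phase.end)
    a = phases.nonbreeding_residency.centroid
    b = phases.breeding_residency.centroid
    return float(dist - great_circle_km(a, b))


@dataclass
class SpeedEstimate:
    start_index: int
    end_index: int
    ground_speed_kmh: float
    speed_error_kmh: float
    retained: bool
    time: pd.Timestamp


def ground_speeds(track: Track,
                  max_leg_hours: float = MAX_SPEED_LEG_HOURS,
                  min_speed_kmh: float = MIN_RETAINED_SPEED_KMH
                  ) -> list[SpeedEstimate]:
    """Per-leg apparent ground speeds with error propagation.

    speed = great-circle distance / elapsed time; speed_error = sum of the
    two fixes' maximum error radii / elapsed time.  Legs longer than
    ``max_leg_hours`` (duty-cycle gaps) are skipped, and estimates below
    ``min_speed_kmh`` are excluded (retained=False) because slow apparent
    speeds can hide undetected stopovers.
    """
    out: list[SpeedEstimate] = []
    times = track.times()
    lats, lons = track.lats(), track.lons()
    for i in range(len(track) - 1):
        dt_h = (times[i + 1] - times[i]).total_seconds() / 3600.0
        if dt_h <= 0 or dt_h > max_leg_hours:
            continue
        dist = haversine_km(lats[i], lons[i], lats[i + 1], lons[i + 1])
        speed = dist / dt_h
        err = (track.fixes[i].error_radius
               + track.fixes[i + 1].error_radius) / dt_h
        out.append(
            SpeedEstimate(
                start_index=i,
                end_index=i + 1,
                ground_speed_kmh=float(speed),
                speed_error_kmh=float(err),
                retained=bool(speed >= min_speed_kmh),
                time=times[i] + (times[i + 1] - times[i]) / 2,
            )
        )
    return out


def whole_days(depart, arrive) -> int:
    """Whole-day difference between two instants on the SGT calendar."""
    d0 = depart if not isinstance(depart, pd.Timestamp) else sgt_date(depart)
    d1 = arrive if not isinstance(arrive, pd.Timestamp) else sgt_date(arrive)
    return (d1 - d0).days


@dataclass
class MigrationSummary:
    """One row of the seasonal timing table for a single bird."""

    bird_id: str
    depart_nonbreeding: object = None  # SGT date
    n_stopovers_north: int = 0
    days_at_stopovers_north: int = 0
    arrive_breeding: object = None
    days_travelling_north: int | None = None
    distance_north_km: float | None = None
    days_at_breeding: int | None = None
    depart_breeding: object = None
    n_stopovers_south: int = 0
    days_at_stopovers_south: int = 0
    arrive_nonbreeding: object = None
    days_travelling_south: int | None = None
    distance_south_km: float | None = None


def summarise_migration(track: Track, segmentation: SegmentationResult,
                        phases: PhaseAssignment) -> MigrationSummary:
    """Populate the seasonal summary (SGT dates, whole-day durations)."""
    s = MigrationSummary(bird_id=track.bird_id)
    by_kind = {p.kind: p for p in phases.phases}
    north = by_kind.get("northward")
    south = by_kind.get("southward")
    breeding = by_kind.get("breeding")
    if north is not None:
        s.depart_nonbreeding = sgt_date(north.start)
        s.arrive_breeding = sgt_date(north.end)
        s.days_travelling_north = whole_days(north.start, north.end)
        s.distance_north_km = migration_distance(
            track, segmentation, north.start, north.end)
        stops = [st for st in segmentation.stopovers
                 if north.start <= st.arrival <= north.end]
        s.n_stopovers_north = len(stops)
        s.days_at_stopovers_north = int(
            sum(whole_days(st.arrival, st.departure) for st in stops))
    if breeding is not None:
        s.days_at_breeding = whole_days(breeding.start, breeding.end)
        s.depart_breeding = sgt_date(breeding.end)
    if south is not None:
        s.arrive_nonbreeding = sgt_date(south.end)
        s.days_travelling_south = whole_days(south.start, south.end)
        s.distance_south_km = migration_distance(
            track, segmentation, south.start, south.end)
        stops = [st for st in segmentation.stopovers
                 if south.start <= st.arrival <= south.end]
        s.n_stopovers_south = len(stops)
        s.days_at_stopovers_south = int(
            sum(whole_days(st.arrival, st.departure) for st in stops))
    return s


def summary_frame(summaries: list[MigrationSummary]) -> pd.DataFrame:
    """Timing-table DataFrame, one row per bird."""
    return pd.DataFrame([vars(s) for s in summaries])
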