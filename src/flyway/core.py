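"""Core containers and spherical geodesy shared by all pipeline stages.

Positions are geographic WGS-ish lat/lon in decimal degrees on a spherical
Earth of radius 6371.0 km (great-circle convention used throughout the
package); times are timezone-aware UTC :class:`pandas.Timestamp`.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Singapore Time, the reporting calendar for migration tables.
SGT_OFFSET_HOURS = 8


class QualityClass(str, enum.Enum):
    """Argos-style location quality classes with nominal error radii."""

    G3 = "G3"
    G2 = "G2"
    G1 = "G1"
    LOW = "LOW"
    TRUTH = "TRUTH"


#: Nominal maximum error radius (km) per quality class; monotone
#: G3 <= 0.25 <= G2 <= 0.5 <= G1 <= 1.5 <= LOW.
CLASS_ERROR_KM = {
    QualityClass.G3: 0.25,
    QualityClass.G2: 0.5,
    QualityClass.G1: 1.5,
    QualityClass.LOW: 5.0,
    QualityClass.TRUTH: 0.0,
}


def _as_utc(t) -> pd.Timestamp:
    ts = pd.Timestamp(t)
    if ts.tzinfo is None:
        return ts.tz_localize("UTC")
    return ts.tz_convert("UTC")


@dataclass(frozen=True)
class GeoPosition:
    """A timestamped geographic position.

    lat in [-90, 90] degrees north, lon in (-180, 180] degrees east,
    time a UTC instant.
    """

    lat: float
    lon: float
    time: pd.Timestamp

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 < self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside (-180, 180]")
        object.__setattr__(self, "time", _as_utc(self.time))


@dataclass(frozen=True)
class TrackFix:
    """One located fix with its error radius and provenance class."""

    position: GeoPosition
    error_radius: float = 0.0
    quality_class: QualityClass = QualityClass.TRUTH
    altitude_true: float | None = None

    def __post_init__(self):
        if self.error_radius < 0:
            raise ValueError("error_radius must be >= 0")
        if self.quality_class is QualityClass.TRUTH and self.error_radius != 0:
            raise ValueError("TRUTH fixes carry error_radius 0")


@dataclass
class Track:
    """An ordered sequence of fixes for one bird."""

    bird_id: str
    species: str = "other"
    tag_type: str = "ptt"
    fixes: list[TrackFix] = field(default_factory=list)
    validate: dataclasses.InitVar[bool] = True

    def __post_init__(self, validate):
        if validate:
            if len(self.fixes) < 2:
                raise ValueError("a track needs at least 2 fixes")
            times = self.times()
            if not (np.diff(times.asi8) > 0).all():
                raise ValueError("fix timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)

    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([f.position.time for f in self.fixes])

    def lats(self) -> np.ndarray:
        return np.array([f.position.lat for f in self.fixes])

    def lons(self) -> np.ndarray:
        return np.array([f.position.lon for f in self.fixes])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.times(),
                "location-lat": self.lats(),
                "location-long": self.lons(),
                "argos:lc": [f.quality_class.value for f in self.fixes],
                "error-radius-km": [f.error_radius for f in self.fixes],
                "height-above-msl": [
                    np.nan if f.altitude_true is None else f.altitude_true
                    for f in self.fixes
                ],
                "individual-local-identifier": self.bird_id,
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, species: str = "other", tag_type: str = "ptt"
    ) -> "Track":
        fixes = []
        for _, row in df.iterrows():
            alt = row.get("height-above-msl", np.nan)
            fixes.append(
                TrackFix(
                    position=GeoPosition(
                        float(row["location-lat"]),
                        float(row["location-long"]),
                        row["timestamp"],
                    ),
                    error_radius=float(row.get("error-radius-km", 0.0)),
                    quality_class=QualityClass(row.get("argos:lc", "TRUTH")),
                    altitude_true=None if pd.isna(alt) else float(alt),
                )
            )
        bird = str(df["individual-local-identifier"].iloc[0])
        return cls(bird_id=bird, species=species, tag_type=tag_type, fixes=fixes)


# --------------------------------------------------------------------------
# Spherical geodesy (great-circle, R = 6371 km)
# --------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km between points given in degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def initial_bearing_deg(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Initial great-circle bearing from point 1 to point 2, degrees from north."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    x = np.sin(dlam) * np.cos(p2)
    y = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    b = np.degrees(np.arctan2(x, y)) % 360.0
    return float(b) if np.ndim(b) == 0 else b


def destination(lat, lon, bearing_deg, distance_km):
    """Point reached from (lat, lon) on the given bearing after distance_km."""
    delta = np.asarray(distance_km) / EARTH_RADIUS_KM
    theta = np.radians(bearing_deg)
    p1 = np.radians(lat)
    l1 = np.radians(lon)
    p2 = np.arcsin(
        np.sin(p1) * np.cos(delta) + np.cos(p1) * np.sin(delta) * np.cos(theta)
    )
    l2 = l1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(p1),
        np.cos(delta) - np.sin(p1) * np.sin(p2),
    )
    return np.degrees(p2), wrap_lon(np.degrees(l2))


def gc_interpolate(lat1, lon1, lat2, lon2, fractions):
    """Points along the great circle between two positions.

    fractions is an array in [0, 1]; returns (lats, lons) arrays.  Uses
    spherical linear interpolation on unit vectors, which is exact for the
    great circle.
    """
    f = np.atleast_1d(np.asarray(fractions, dtype=float))
    v1 = _unit_vector(lat1, lon1)
    v2 = _unit_vector(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))
    if omega < 1e-12:
        lats = np.full_like(f, lat1)
        lons = np.full_like(f, lon1)
        return lats, lons
    s = np.sin(omega)
    v = (
        np.sin((1 - f)[:, None] * omega) / s * v1[None, :]
        + np.sin(f[:, None] * omega) / s * v2[None, :]
    )
    lats = np.degrees(np.arcsin(np.clip(v[:, 2], -1.0, 1.0)))
    lons = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    return lats, wrap_lon(lons)


def _unit_vector(lat, lon):
    p, l = np.radians(lat), np.radians(lon)
    return np.array([np.cos(p) * np.cos(l), np.cos(p) * np.sin(l), np.sin(p)])


def wrap_lon(lon):
    """Wrap longitudes into (-180, 180]."""
    w = -((-np.asarray(lon) + 180.0) % 360.0 - 180.0)
    out = np.where(w == -180.0, 180.0, w)
    return float(out) if np.ndim(out) == 0 else out


def centroid_latlon(lats: Iterable[float], lons: Iterable[float]) -> tuple[float, float]:
    """Spherical centroid (mean unit vector) of a point cloud, degrees."""
    lats = np.asarray(list(lats), dtype=float)
    lons = np.asarray(list(lons), dtype=float)
    p, l = np.radians(lats), np.radians(lons)
    x = np.cos(p) * np.cos(l)
    y = np.cos(p) * np.sin(l)
    z = np.sin(p)
    v = np.array([x.mean(), y.mean(), z.mean()])
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate centroid (antipodal cancellation)")
    v /= n
    return float(np.degrees(np.arcsin(v[2]))), float(
        wrap_lon(np.degrees(np.arctan2(v[1], v[0])))
    )


def to_sgt(t: pd.Timestamp) -> pd.Timestamp:
    """Convert a UTC instant to Singapore Time (UTC+8), the reporting calendar."""
    return _as_utc(t).tz_convert("Etc/GMT-8")


def sgt_date(t: pd.Timestamp):
    return to_sgt(t).date()
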