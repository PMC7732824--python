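"""File formats, configuration and pipeline orchestration.

On-disk conventions: timestamps are ISO-8601 UTC, coordinates signed
decimal degrees with longitude in (-180, 180]; tracks are Movebank-style
CSV, geolocator streams two/three-column CSVs, elevation grids ESRI ASCII,
wind fields NetCDF (classic format).  Singapore Time appears only in report
tables.  :func:`run_pipeline` binds the stages simulate -> geolocate ->
segment -> metrics -> annotate -> compare and writes a manifest with the
package version, seeds and a hash of the configuration and all numeric
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__ as _version
from . import env, geolocation, metrics, segmentation, stats, synthetic
from .core import Track

log = logging.getLogger("flyway")

TRACK_COLUMNS = [
    "timestamp", "location-lat", "location-long", "argos:lc",
    "error-radius-km", "height-above-msl", "individual-local-identifier",
]


class SchemaError(ValueError):
    """A file violated its documented schema (names file/line/column)."""


# ---------------------------------------------------------------------------
# Track CSV (Movebank-style)
# ---------------------------------------------------------------------------


def write_track_csv(track: Track, path) -> None:
    df = track.to_dataframe()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df["location-lat"] = df["location-lat"].round(6)
    df["location-long"] = df["location-long"].round(6)
    df.to_csv(path, index=False)


def read_track_csv(path, species: str = "other", tag_type: str = "ptt") -> Track:
    df = pd.read_csv(path)
    for col in ("timestamp", "location-lat", "location-long",
                "individual-local-identifier"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True,
                                         format="ISO8601")
    except (ValueError, TypeError) as exc:
        bad = _first_bad_timestamp(df["timestamp"])
        raise SchemaError(
            f"{path}: malformed timestamp at row {bad}, column 'timestamp'"
        ) from exc
    return Track.from_dataframe(df, species=species, tag_type=tag_type)


def _first_bad_timestamp(col) -> int:
    for i, v in enumerate(col):
        try:
            pd.to_datetime(v, utc=True, format="ISO8601")
        except (ValueError, TypeError):
            return i + 2  # 1-based plus header line
    return -1


# ---------------------------------------------------------------------------
# Geolocator streams
# ---------------------------------------------------------------------------


def write_series_csv(series: pd.Series, path, value_name: str) -> None:
    df = pd.DataFrame({
        "timestamp": series.index.strftime("%Y-%m-%dT%H:%M:%SZ"),
        value_name: series.to_numpy(),
    })
    df.to_csv(path, index=False)


def read_series_csv(path, value_name: str) -> pd.Series:
    df = pd.read_csv(path)
    if "timestamp" not in df.columns or value_name not in df.columns:
        raise SchemaError(f"{path}: expected columns timestamp,{value_name}")
    idx = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return pd.Series(df[value_name].to_numpy(), index=pd.DatetimeIndex(idx),
                     name=value_name)


def read_light(path) -> pd.Series:
    """Light series from a CSV (timestamp,light) or .lux-like two-column
    whitespace/tab text (time, light)."""
    path = Path(path)
    if path.suffix.lower() == ".lux":
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=["date", "time", "light"])
        idx = pd.to_datetime(df["date"] + " " + df["time"], utc=True,
                             dayfirst=True)
        return pd.Series(df["light"].to_numpy(), index=pd.DatetimeIndex(idx),
                         name="light")
    return read_series_csv(path, "light")


# ---------------------------------------------------------------------------
# DEM: ESRI ASCII grid (cell-centre registered via ll corner + cellsize)
# ---------------------------------------------------------------------------


def write_dem(grid: synthetic.ElevationGrid, path,
              nodata: float = -9999.0) -> None:
    cs_lat = np.diff(grid.lat_centers)
    cs_lon = np.diff(grid.lon_centers)
    cell = float(cs_lat.mean())
    if not (np.allclose(cs_lat, cell, atol=1e-9)
            and np.allclose(cs_lon, cell, atol=1e-9)):
        raise ValueError("ESRI ASCII needs a square uniform grid")
    with open(path, "w") as fh:
        fh.write(f"ncols {len(grid.lon_centers)}\n")
        fh.write(f"nrows {len(grid.lat_centers)}\n")
        fh.write(f"xllcorner {grid.lon_centers[0] - cell / 2:.10g}\n")
        fh.write(f"yllcorner {grid.lat_centers[0] - cell / 2:.10g}\n")
        fh.write(f"cellsize {cell:.10g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in grid.elevation[::-1]:  # north to south
            fh.write(" ".join(f"{v:.3f}" for v in row) + "\n")


def read_dem(path) -> synthetic.ElevationGrid:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines[:6]):
        key, val = line.split()
        header[key.lower()] = float(val)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    data = np.loadtxt(lines[6:])
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise SchemaError(f"{path}: grid body is {data.shape}, header says "
                          f"({nrows}, {ncols})")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    lats = header["yllcorner"] + cell * (np.arange(nrows) + 0.5)
    lons = header["xllcorner"] + cell * (np.arange(ncols) + 0.5)
    return synthetic.ElevationGrid(lats, lons, data[::-1])


# ---------------------------------------------------------------------------
# Wind: gridded NetCDF (classic format via the scipy engine)
# ---------------------------------------------------------------------------


def write_wind(field: synthetic.WindField, path) -> None:
    times = field.times.tz_convert("UTC").tz_localize(None)
    data = {}
    for lev in synthetic.LEVELS:
        data[f"u_{lev}"] = (("time", "lat", "lon"), field.u[lev])
        data[f"v_{lev}"] = (("time", "lat", "lon"), field.v[lev])
    ds = xr.Dataset(
        data,
        coords={"time": times, "lat": field.lat_centers,
                "lon": field.lon_centers},
        attrs={"units": "km/h", "convention": "u eastward, v northward"},
    )
    ds.to_netcdf(path, engine="scipy")


def read_wind(path) -> synthetic.WindField:
    with xr.open_dataset(path, engine="scipy") as ds:
        times = pd.DatetimeIndex(ds["time"].values).tz_localize("UTC")
        u = {lev: ds[f"u_{lev}"].values.copy() for lev in synthetic.LEVELS}
        v = {lev: ds[f"v_{lev}"].values.copy() for lev in synthetic.LEVELS}
        return synthetic.WindField(
            times=times,
            lat_centers=ds["lat"].values.copy(),
            lon_centers=ds["lon"].values.copy(),
            u=u, v=v,
        )


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------


def write_geojson(path, lats, lons, properties: dict | None = None) -> None:
    """LineString export of a located track."""
    feature = {
        "type": "Feature",
        "properties": properties or {},
        "geometry": {
            "type": "LineString",
            "coordinates": [
                [round(float(lo), 6), round(float(la), 6)]
                for la, lo in zip(lats, lons)
            ],
        },
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def write_stopover_csv(result: segmentation.SegmentationResult, path) -> None:
    rows = []
    for s in result.residencies + result.stopovers:
        rows.append({
            "kind": "residency" if s.is_terminal else "stopover",
            "centroid-lat": round(s.centroid.lat, 6),
            "centroid-long": round(s.centroid.lon, 6),
            "arrival": s.arrival.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "departure": s.departure.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "duration-days": round(s.duration_days, 3),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class PipelineConfig(BaseModel):
    """All pipeline tunables; defaults follow the field protocol values."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_birds: int = 4
    start_time: str = "2019-04-01T00:00:00Z"
    flight_ground_speed_kmh: float = 55.0
    flight_altitude_masl: float = 4000.0
    duty_cycle_hours: tuple[float, float] = (10.0, 48.0)
    twilight_shading_gamma: tuple[float, float] = (2.0, 0.5)
    light_threshold: float = 1.0
    light_threshold_elevation_deg: float = -3.5
    initial_residency_days: float = 20.0
    final_residency_days: float = 10.0
    stopover_days: float = 5.0
    stopover_radius_km: float = 150.0
    stopover_min_days: float = 3.0
    speed_filter_kmh: float = 20.0
    speed_prior_shape: float = 2.2
    speed_prior_rate: float = 0.08
    lapse_c_per_km: float = 6.5
    elevation_bin_deg: float = 0.1
    breeding_latitude: float = 30.0
    crest_elevation_masl: float = 4000.0
    n_resamples: int = 9999
    mcmc_n_init: int = 1000
    mcmc_n_tune: int = 300
    mcmc_n_tune_runs: int = 3
    mcmc_n_iter: int = 2000
    geolocation_enabled: bool = True
    wind_mean_u_kmh: float = 20.0
    wind_mean_v_kmh: float = 5.0
    wind_perturbation_kmh: float = 10.0
    out_dir: str = "pipeline-out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

# Route templates (lat, lon): a trans-Himalayan crossing near 92 degE and an
# eastern ascent via Yunnan, both Singapore -> Qinghai-Tibet Plateau.
HIMALAYAN_WAYPOINTS = [(1.45, 103.73), (16.5, 96.5), (33.0, 92.0)]
EASTERN_WAYPOINTS = [(1.45, 103.73), (21.0, 101.0), (35.0, 97.0)]


def _plan_for_bird(cfg: PipelineConfig, i: int) -> synthetic.SimulationPlan:
    himalayan = i % 2 == 0
    waypoints = HIMALAYAN_WAYPOINTS if himalayan else EASTERN_WAYPOINTS
    return synthetic.SimulationPlan(
        waypoints=list(waypoints),
        stopover_durations_days=[cfg.stopover_days] * (len(waypoints) - 2),
        flight_ground_speed_kmh=cfg.flight_ground_speed_kmh,
        flight_altitude_masl=cfg.flight_altitude_masl,
        duty_cycle_hours=cfg.duty_cycle_hours,
        twilight_shading_gamma=cfg.twilight_shading_gamma,
        seed=cfg.seed + 101 * i,
        start_time=pd.Timestamp(cfg.start_time) + pd.Timedelta(days=2 * i),
        initial_residency_days=cfg.initial_residency_days,
        final_residency_days=cfg.final_residency_days,
        light_threshold_elevation_deg=cfg.light_threshold_elevation_deg,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain on a synthetic cohort and write artifacts.

    Returns a dict with the in-memory results and the manifest.  Half the
    cohort follows the trans-Himalayan route template and half the eastern
    ascent, so the comparison stage always has both groups.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "flyway",
        "version": _version,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "stages": {},
    }
    numeric_outputs: dict = {}
    results: dict = {"tracks": [], "argos": [], "summaries": [],
                     "segmentations": []}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            dt = time.perf_counter() - t0
            manifest["stages"][name] = round(dt, 3)
            log.info("stage %-10s %6.2f s", name, dt)
        return done

    finish = stage("simulate")
    routes = []
    for i in range(config.n_birds):
        plan = _plan_for_bird(config, i)
        truth = synthetic.simulate_track(plan)
        argos = synthetic.degrade_to_argos(truth, plan)
        routes.append("himalayan" if i % 2 == 0 else "eastern")
        results["tracks"].append((plan, truth))
        results["argos"].append(argos)
        write_track_csv(argos, out_dir / f"track-{argos.bird_id}.csv")
    dem = synthetic.make_dem()
    write_dem(dem, out_dir / "dem.asc")
    wspec = synthetic.WindFieldSpec(
        time_start=pd.Timestamp(config.start_time),
        time_end=pd.Timestamp(config.start_time) + pd.Timedelta(days=120),
        levels={
            "surface": synthetic.WindLevelSpec(
                config.wind_mean_u_kmh * 0.4, config.wind_mean_v_kmh * 0.4,
                config.wind_perturbation_kmh),
            "mb850": synthetic.WindLevelSpec(
                config.wind_mean_u_kmh * 0.8, config.wind_mean_v_kmh * 0.8,
                config.wind_perturbation_kmh),
            "mb700": synthetic.WindLevelSpec(
                config.wind_mean_u_kmh, config.wind_mean_v_kmh,
                config.wind_perturbation_kmh),
        },
    )
    wind = synthetic.make_wind_field(wspec, seed=config.seed + 7)
    write_wind(wind, out_dir / "wind.nc")
    finish()

    if config.geolocation_enabled:
        finish = stage("geolocate")
        plan0, truth0 = results["tracks"][0]
        light = synthetic.simulate_light(truth0, plan0)
        write_series_csv(light, out_dir / "light-bird0.csv", "light")
        events = geolocation.detect_twilights(light,
                                              threshold=config.light_threshold)
        site = plan0.waypoints[0]
        cal_events = [
            ev for ev in events
            if ev.time <= plan0.start_time
            + pd.Timedelta(days=plan0.initial_residency_days)
        ]
        calib = geolocation.calibrate(cal_events, site[0], site[1])
        grouping = geolocation.group_residency(events, calib)
        refined = geolocation.refine_track(
            events, grouping, calib, deployment_site=site,
            speed_prior=geolocation.SpeedPrior(config.speed_prior_shape,
                                               config.speed_prior_rate),
            n_init=config.mcmc_n_init, n_tune=config.mcmc_n_tune,
            n_tune_runs=config.mcmc_n_tune_runs, n_iter=config.mcmc_n_iter,
            seed=config.seed + 13,
        )
        results["geolocation"] = {"calibration": calib, "refined": refined}
        write_geojson(out_dir / "geolocation-bird0.geojson",
                      [e.lat for e in refined], [e.lon for e in refined],
                      {"bird": truth0.bird_id})
        numeric_outputs["geolocation_median_lat"] = [
            round(e.lat, 6) for e in refined]
        numeric_outputs["geolocation_median_lon"] = [
            round(e.lon, 6) for e in refined]
        finish()

    finish = stage("segment")
    for argos in results["argos"]:
        seg = segmentation.detect_stopovers(
            argos, radius_km=config.stopover_radius_km,
            min_days=config.stopover_min_days)
        results["segmentations"].append(seg)
        write_stopover_csv(seg, out_dir / f"stopovers-{argos.bird_id}.csv")
    finish()

    finish = stage("metrics")
    distances = []
    for argos, seg in zip(results["argos"], results["segmentations"]):
        phases = segmentation.assign_phases(
            argos, seg, breeding_latitude=config.breeding_latitude)
        summary = metrics.summarise_migration(argos, seg, phases)
        results["summaries"].append(summary)
        distances.append(summary.distance_north_km)
    metrics.summary_frame(results["summaries"]).to_csv(
        out_dir / "migration-summary.csv", index=False)
    numeric_outputs["distance_north_km"] = [
        None if d is None else round(d, 1) for d in distances]
    finish()

    finish = stage("annotate")
    support_rows = []
    profiles = []
    for argos, route in zip(results["argos"], routes):
        ann = env.annotate_wind(argos, wind)
        ann["route"] = route
        support_rows.append(ann)
        prof = env.min_elevation_profile(argos, dem,
                                         bin_deg=config.elevation_bin_deg)
        profiles.append(prof.mean_min_elevation)
    annotated = pd.concat(support_rows, ignore_index=True)
    annotated.to_csv(out_dir / "wind-annotation.csv", index=False)
    numeric_outputs["mean_min_elevation_masl"] = [
        round(p, 1) for p in profiles]
    finish()

    finish = stage("compare")
    him = [d for d, r in zip(distances, routes)
           if r == "himalayan" and d is not None]
    east = [d for d, r in zip(distances, routes)
            if r == "eastern" and d is not None]
    comparisons = {}
    if len(him) >= 2 and len(east) >= 2:
        pt = stats.permutation_test(him, east,
                                    n_resamples=config.n_resamples,
                                    seed=config.seed + 23)
        comparisons["distance_north"] = {"Z": round(pt.z, 4),
                                         "P": round(pt.p, 4)}
    flight = annotated[(annotated["level"] == "mb700")
                       & annotated["ground_speed_kmh"].ge(
                           config.speed_filter_kmh)]
    if len(flight) >= 3:
        reg = stats.fit_speed_wind(flight["ground_speed_kmh"],
                                   flight["support_kmh"], response="ground")
        comparisons["ground_speed_on_support_mb700"] = {
            "slope": round(reg.coefficients["support"][0], 4),
            "R2": round(reg.r_squared, 4),
        }
    pd.DataFrame(comparisons).to_json(out_dir / "comparisons.json")
    numeric_outputs["comparisons"] = comparisons
    finish()

    blob = json.dumps(numeric_outputs, sort_keys=True, default=str)
    manifest["outputs_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
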