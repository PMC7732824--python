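"""Threshold-method geolocation: detection, calibration, inversion, grouping,
and MCMC refinement, all exercised on forward-simulated light."""

import numpy as np
import pandas as pd
import pytest

from flyway import geolocation, solar, synthetic
from flyway.core import haversine_km
from flyway.geolocation import SpeedPrior, TwilightEvent
from flyway.synthetic import SimulationPlan

SG = (1.45, 103.73)


def stationary_events(site, start, days, shading=(0.0, 0.0), seed=0,
                      threshold_elev=-3.5):
    plan = SimulationPlan(
        waypoints=[site, (site[0] + 0.8, site[1])],
        stopover_durations_days=[],
        twilight_shading_gamma=shading,
        initial_residency_days=float(days), final_residency_days=0.5,
        start_time=start, seed=seed,
        light_threshold_elevation_deg=threshold_elev)
    track = synthetic.simulate_track(plan)
    light = synthetic.simulate_light(track, plan)
    cutoff = plan.start_time + pd.Timedelta(days=days)
    ev = [e for e in geolocation.detect_twilights(light) if e.time <= cutoff]
    return plan, light, ev


class TestDetectTwilights:
    def test_day_length_matches_solar_oracle(self):
        _, _, ev = stationary_events(SG, "2019-01-01T00:00:00Z", 5)
        rises = [e.time for e in ev if e.kind == "sunrise"]
        sets_ = [e.time for e in ev if e.kind == "sunset"]
        rise = rises[0]
        set_ = next(t for t in sets_ if t > rise)
        detected = (set_ - rise).total_seconds() / 60.0
        r_o = solar.crossing_time(rise.normalize(), *SG, -3.5, True)
        if r_o is None or abs((r_o - rise).total_seconds()) > 43200:
            r_o = solar.crossing_time(rise.normalize()
                                      - pd.Timedelta(days=1), *SG, -3.5, True)
        s_o = solar.crossing_time(set_.normalize(), *SG, -3.5, False)
        oracle = (s_o - r_o).total_seconds() / 60.0
        assert detected == pytest.approx(oracle % 1440.0, abs=5.0)

    def test_constant_darkness_yields_no_events(self):
        idx = pd.date_range("2019-01-01", periods=600, freq="5min", tz="UTC")
        light = pd.Series(0.3, index=idx)
        assert geolocation.detect_twilights(light) == []
        gaps = geolocation.twilight_gaps([], 2.0, idx[0])
        assert len(gaps) == 2

    def test_monotone_scaling_invariance(self):
        _, light, _ = stationary_events(SG, "2019-01-01T00:00:00Z", 3)
        ev1 = geolocation.detect_twilights(light, threshold=1.0)
        # scaling light by 10 shifts log by log(10); shifting the threshold
        # accordingly leaves every crossing time unchanged
        ev2 = geolocation.detect_twilights(light * 10.0,
                                           threshold=1.0 + np.log(10.0))
        assert len(ev1) == len(ev2)
        for a, b in zip(ev1, ev2):
            assert a.kind == b.kind
            assert abs((a.time - b.time).total_seconds()) < 1.0

    def test_alternating_kinds(self, stationary_events):
        kinds = [e.kind for e in stationary_events]
        for a, b in zip(kinds[:-1], kinds[1:]):
            assert a != b


class TestCalibrate:
    def test_zero_noise_angle_recovery(self):
        _, _, ev = stationary_events((45.0, 10.0), "2019-01-01T00:00:00Z", 20)
        cal = geolocation.calibrate(ev, 45.0, 10.0)
        assert cal.sun_elevation_angle == pytest.approx(-3.5, abs=0.2)
        assert cal.degenerate  # residuals all ~zero -> point-mass tolerance

    def test_gamma_error_recovery(self, calibration):
        # forward noise was gamma(shape 2, rate 0.5) minutes
        assert calibration.gamma_shape == pytest.approx(2.0, rel=0.5)
        assert calibration.gamma_rate == pytest.approx(0.5, rel=0.6)
        assert not calibration.degenerate

    def test_refuses_short_series(self):
        _, _, ev = stationary_events(SG, "2019-01-01T00:00:00Z", 4)
        with pytest.raises(ValueError, match="10"):
            geolocation.calibrate(ev, *SG)


class TestThresholdLocation:
    def test_midwinter_inversion(self):
        _, _, ev = stationary_events((45.0, 10.0), "2018-12-20T00:00:00Z", 15)
        cal = geolocation.calibrate(ev, 45.0, 10.0)
        ests = geolocation.locate(ev, cal)
        lats = np.array([e.lat for e in ests])
        lons = np.array([e.lon for e in ests])
        assert abs(np.nanmedian(lons) - 10.0) < 0.5
        assert abs(np.nanmedian(lats) - 45.0) < 1.0
        assert not any(e.outlier for e in ests)

    def test_noon_translation_moves_longitude_only(self, calibration):
        rise = pd.Timestamp("2019-01-10T22:59:00Z")
        set_ = pd.Timestamp("2019-01-11T11:08:00Z")
        a = geolocation.threshold_location(rise, set_, calibration)
        b = geolocation.threshold_location(rise + pd.Timedelta(hours=1),
                                           set_ + pd.Timedelta(hours=1),
                                           calibration)
        # exact up to the equation-of-time drift over one hour (~0.004 deg)
        assert b.lon - a.lon == pytest.approx(-15.0, abs=0.01)
        if np.isfinite(a.lat) and np.isfinite(b.lat):
            assert b.lat == pytest.approx(a.lat, abs=0.2)

    def test_equinox_latitude_flagged(self):
        _, _, ev = stationary_events((30.0, 100.0), "2019-03-12T00:00:00Z", 14)
        cal = geolocation.Calibration(sun_elevation_angle=-3.5,
                                      gamma_shape=None, gamma_rate=None,
                                      degenerate=True)
        ests = geolocation.locate(ev, cal)
        near_equinox = [e for e in ests
                        if abs((e.time - pd.Timestamp("2019-03-20T12:00:00Z",
                                                      tz="UTC")
                                ).total_seconds()) < 5 * 86400]
        assert near_equinox
        assert all(e.latitude_flagged for e in near_equinox)

    def test_latitude_error_grows_towards_equinox(self):
        # seasonal sweep: same site, increasing proximity to the equinox
        errs = []
        for start in ("2019-01-05", "2019-02-05", "2019-03-05"):
            _, _, ev = stationary_events((40.0, 20.0),
                                         f"{start}T00:00:00Z", 10)
            cal = geolocation.Calibration(sun_elevation_angle=-3.5,
                                          gamma_shape=None, gamma_rate=None,
                                          degenerate=True)
            ests = geolocation.locate(ev, cal)
            lats = np.array([e.lat for e in ests if np.isfinite(e.lat)])
            lons = np.array([e.lon for e in ests])
            errs.append((np.nanstd(lats), np.nanstd(lons)))
        lat_spread = [e[0] for e in errs]
        lon_spread = [e[1] for e in errs]
        assert lat_spread[0] < lat_spread[-1]  # monotone degradation
        assert max(lon_spread) < 0.5  # longitude stays equinox-robust


class TestGroupResidency:
    def test_stationary_month_is_single_group(self, stationary_events,
                                              calibration):
        month = [e for e in stationary_events
                 if e.time < pd.Timestamp("2019-02-01", tz="UTC")]
        g = geolocation.group_residency(month, calibration)
        assert g.n_groups == 1
        assert not g.movement.any()

    def test_two_sites_two_groups_boundary_within_a_day(self, calibration):
        plan = SimulationPlan(
            waypoints=[(10.0, 100.0), (20.0, 100.0)],
            stopover_durations_days=[],
            twilight_shading_gamma=(2.0, 0.5),
            initial_residency_days=10.0, final_residency_days=10.0,
            start_time="2019-01-05T00:00:00Z", seed=4)
        track = synthetic.simulate_track(plan)
        ev = geolocation.detect_twilights(synthetic.simulate_light(track, plan))
        g = geolocation.group_residency(ev, calibration)
        resident_labels = set(g.labels[~g.movement].tolist())
        assert len(resident_labels) == 2
        move_time = plan.schedule()[1]["start"]
        boundary = [e.time for e, m in zip(ev, g.movement) if m]
        if boundary:  # movement twilights sit at the true changepoint
            err = min(abs((t - move_time).total_seconds()) for t in boundary)
            assert err < 2 * 86400
        # and the group switch happens within a day of the move
        switch_idx = int(np.nonzero(np.diff(g.labels) != 0)[0][0]) + 1
        assert abs((ev[switch_idx].time - move_time).total_seconds()) \
            < 2 * 86400

    def test_one_day_excursion_discarded(self, calibration):
        plan = SimulationPlan(
            waypoints=[(10.0, 100.0), (12.0, 109.0), (10.0, 100.0)],
            stopover_durations_days=[1.0],
            twilight_shading_gamma=(2.0, 0.5),
            flight_ground_speed_kmh=110.0,
            initial_residency_days=10.0, final_residency_days=10.0,
            start_time="2019-01-05T00:00:00Z", seed=6)
        track = synthetic.simulate_track(plan)
        ev = geolocation.detect_twilights(synthetic.simulate_light(track, plan))
        g = geolocation.group_residency(ev, calibration)
        # no residency group sits at the excursion site: every excursion
        # twilight is either movement or merged into the home-site group
        exc = [p for p in plan.schedule()
               if p["kind"] == "residency" and p["waypoint"] == 1][0]
        for i, e in enumerate(ev):
            if exc["start"] <= e.time <= exc["end"] and not g.movement[i]:
                run = g.labels == g.labels[i]
                span = (max(e2.time for e2, r in zip(ev, run) if r)
                        - min(e2.time for e2, r in zip(ev, run) if r))
                assert span >= pd.Timedelta(days=2)


class TestRefineTrack:
    def test_endpoints_fixed_to_deployment(self, calibration):
        plan = SimulationPlan(
            waypoints=[(10.0, 100.0), (20.0, 95.0), (10.0, 100.0)],
            stopover_durations_days=[8.0],
            twilight_shading_gamma=(2.0, 0.5),
            initial_residency_days=8.0, final_residency_days=8.0,
            start_time="2019-01-05T00:00:00Z", seed=8)
        track = synthetic.simulate_track(plan)
        ev = geolocation.detect_twilights(synthetic.simulate_light(track, plan))
        g = geolocation.group_residency(ev, calibration)
        out = geolocation.refine_track(
            ev, g, calibration, deployment_site=(10.0, 100.0),
            n_init=100, n_tune=60, n_tune_runs=2, n_iter=200, seed=1)
        assert (out[0].lat, out[0].lon) == (10.0, 100.0)
        assert (out[-1].lat, out[-1].lon) == (10.0, 100.0)
        # medians sit inside their credible intervals by construction
        for e in out:
            assert e.lat_ci[0] <= e.lat <= e.lat_ci[1]
            assert e.lon_ci[0] <= e.lon <= e.lon_ci[1]

    def test_refinement_recovers_second_site(self, calibration):
        plan = SimulationPlan(
            waypoints=[(10.0, 100.0), (20.0, 100.0)],
            stopover_durations_days=[],
            twilight_shading_gamma=(2.0, 0.5),
            initial_residency_days=10.0, final_residency_days=10.0,
            start_time="2019-01-05T00:00:00Z", seed=4)
        track = synthetic.simulate_track(plan)
        ev = geolocation.detect_twilights(synthetic.simulate_light(track, plan))
        g = geolocation.group_residency(ev, calibration)
        out = geolocation.refine_track(
            ev, g, calibration, deployment_site=(10.0, 100.0),
            n_init=300, n_tune=150, n_tune_runs=3, n_iter=600, seed=2,
            fix_last=False)
        dest = out[-1]
        assert haversine_km(dest.lat, dest.lon, 20.0, 100.0) < 150.0

    def test_speed_prior_excludes_implausible_jumps(self, calibration):
        # raw threshold estimates near the equinox scatter wildly in
        # latitude; the refined track must not imply extreme speeds
        plan = SimulationPlan(
            waypoints=[(10.0, 100.0), (25.0, 95.0)],
            stopover_durations_days=[],
            twilight_shading_gamma=(2.0, 0.5),
            initial_residency_days=12.0, final_residency_days=12.0,
            start_time="2019-03-05T00:00:00Z", seed=9)
        track = synthetic.simulate_track(plan)
        ev = geolocation.detect_twilights(synthetic.simulate_light(track, plan))
        raw = geolocation.locate(ev, calibration)
        g = geolocation.group_residency(ev, calibration)
        out = geolocation.refine_track(
            ev, g, calibration, deployment_site=(10.0, 100.0),
            n_init=300, n_tune=150, n_tune_runs=3, n_iter=600, seed=3,
            fix_last=False)

        def max_speed(points):
            best = 0.0
            for a, b in zip(points[:-1], points[1:]):
                dt_h = (b[2] - a[2]).total_seconds() / 3600.0
                if dt_h > 1.0 and np.isfinite(a[0]) and np.isfinite(b[0]):
                    best = max(best, haversine_km(a[0], a[1], b[0], b[1])
                               / dt_h)
            return best

        raw_pts = [(e.lat, e.lon, e.time) for e in raw]
        ref_pts = [(e.lat, e.lon, e.time) for e in out]
        prior_q999 = SpeedPrior().shape / SpeedPrior().rate * 10
        assert max_speed(ref_pts) < max_speed(raw_pts)
        assert max_speed(ref_pts) < prior_q999


def test_forward_inverse_median_error_under_150km(calibration,
                                                  stationary_events):
    """Shaded light at a stationary tropical site inverts, away from the
    equinoxes, to within the method's 150 km working error."""
    jan_feb = [e for e in stationary_events
               if e.time < pd.Timestamp("2019-03-01", tz="UTC")]
    ests = geolocation.locate(jan_feb, calibration)
    good = [e for e in ests if not e.latitude_flagged]
    errs = [haversine_km(e.lat, e.lon, *SG) for e in good]
    assert np.median(errs) < 150.0
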