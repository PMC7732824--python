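import numpy as np
import pandas as pd
import pytest

from flyway import solar, synthetic
from flyway.core import QualityClass, haversine_km
from flyway.synthetic import RidgeSpec, SimulationPlan, WindFieldSpec, WindLevelSpec

SG = (1.45, 103.73)


def two_point_plan(dist_target_km=1100.0, **kw):
    # waypoint pair ~dist_target_km apart due north
    from flyway.core import destination
    lat2, lon2 = destination(10.0, 100.0, 0.0, dist_target_km)
    defaults = dict(
        waypoints=[(10.0, 100.0), (float(lat2), float(lon2))],
        stopover_durations_days=[],
        flight_ground_speed_kmh=55.0,
        initial_residency_days=2.0,
        final_residency_days=2.0,
        start_time="2019-04-01T00:00:00Z",
        seed=0,
    )
    defaults.update(kw)
    return SimulationPlan(**defaults)


class TestSimulateTrack:
    def test_flight_time_is_distance_over_speed(self):
        plan = two_point_plan(1100.0)
        sched = plan.schedule()
        flight = [p for p in sched if p["kind"] == "flight"][0]
        hours = (flight["end"] - flight["start"]).total_seconds() / 3600.0
        assert hours == pytest.approx(1100.0 / 55.0, rel=1e-6)

    def test_stopover_interval_is_stationary(self):
        plan = SimulationPlan(
            waypoints=[SG, (16.5, 96.5), (33.0, 92.0)],
            stopover_durations_days=[5.0],
            initial_residency_days=2.0, final_residency_days=2.0,
            seed=1,
        )
        track = synthetic.simulate_track(plan)
        stop = [p for p in plan.schedule()
                if p["kind"] == "residency" and p["waypoint"] == 1][0]
        times = track.times()
        sel = (times >= stop["start"]) & (times <= stop["end"])
        d = haversine_km(track.lats()[sel], track.lons()[sel], 16.5, 96.5)
        assert (stop["end"] - stop["start"]) >= pd.Timedelta(days=5)
        assert np.max(d) < 1.0

    def test_seeded_determinism(self):
        plan = two_point_plan(seed=7)
        a = synthetic.simulate_track(plan)
        b = synthetic.simulate_track(two_point_plan(seed=7))
        assert np.array_equal(a.lats(), b.lats())
        assert np.array_equal(a.lons(), b.lons())

    def test_track_length_conserves_leg_sum(self):
        plan = SimulationPlan(
            waypoints=[SG, (16.5, 96.5), (33.0, 92.0)],
            stopover_durations_days=[0.0],
            initial_residency_days=0.0, final_residency_days=0.0,
            stopover_jitter_km=0.0, seed=2,
        )
        track = synthetic.simulate_track(plan)
        lats, lons = track.lats(), track.lons()
        total = np.sum(haversine_km(lats[:-1], lons[:-1], lats[1:], lons[1:]))
        assert total == pytest.approx(plan.total_great_circle_km(), rel=1e-3)

    def test_rejects_bad_plans(self):
        with pytest.raises(ValueError):
            SimulationPlan(waypoints=[SG, SG], stopover_durations_days=[])
        with pytest.raises(ValueError):
            two_point_plan(flight_ground_speed_kmh=-1.0)
        with pytest.raises(ValueError):
            SimulationPlan(waypoints=[SG, (10.0, 100.0)],
                           stopover_durations_days=[-1.0])


class TestArgosDegradation:
    def test_on_window_count_over_58_hours(self):
        plan = two_point_plan(1100.0, initial_residency_days=0.0,
                              final_residency_days=40.0 / 24.0)
        track = synthetic.simulate_track(plan)
        span_h = (track.times()[-1] - track.times()[0]).total_seconds() / 3600
        assert span_h == pytest.approx(60.0, abs=1.0)
        argos = synthetic.degrade_to_argos(track, plan)
        hours = (argos.times().asi8 - track.times().asi8[0]) / 3.6e12
        windows = set((hours // 58.0).astype(int))
        assert windows == {0, 1}

    def test_class_error_bounds_never_exceeded(self, migration_truth,
                                               migration_plan):
        argos = synthetic.degrade_to_argos(migration_truth, migration_plan)
        truth_by_time = {f.position.time: f for f in migration_truth.fixes}
        for f in argos.fixes:
            t = truth_by_time[f.position.time]
            d = haversine_km(f.position.lat, f.position.lon,
                             t.position.lat, t.position.lon)
            assert d <= f.error_radius + 1e-9
            if f.quality_class is QualityClass.G3:
                assert d <= 0.25 + 1e-9

    def test_noisier_class_mixture_gives_larger_displacement(self):
        plan_g3 = two_point_plan(seed=5, initial_residency_days=30.0,
                                 argos_class_mixture={"G3": 1.0})
        plan_g1 = two_point_plan(seed=5, initial_residency_days=30.0,
                                 argos_class_mixture={"G1": 1.0})
        truth = synthetic.simulate_track(plan_g3)

        def mean_disp(plan):
            argos = synthetic.degrade_to_argos(truth, plan, seed=99)
            tt = {f.position.time: f for f in truth.fixes}
            d = [haversine_km(f.position.lat, f.position.lon,
                              tt[f.position.time].position.lat,
                              tt[f.position.time].position.lon)
                 for f in argos.fixes]
            return np.mean(d)

        assert mean_disp(plan_g1) > mean_disp(plan_g3)

    def test_empty_duty_cycle_warns(self):
        # a track slice that falls entirely inside the tag's off period
        plan_off = two_point_plan(duty_cycle_hours=(10.0, 1000.0))
        track = synthetic.simulate_track(plan_off)
        short = type(track)(bird_id="x", fixes=track.fixes[12:20])
        with pytest.warns(UserWarning):
            out = synthetic.degrade_to_argos(short, plan_off, seed=1)
        assert len(out.fixes) == 0


class TestLightModel:
    def test_zero_shading_crossings_match_solar_oracle(self):
        plan = two_point_plan(initial_residency_days=4.0,
                              twilight_shading_gamma=(0.0, 0.0))
        track = synthetic.simulate_track(plan)
        light = synthetic.simulate_light(track, plan)
        logl = np.log(light.to_numpy())
        above = logl > 1.0
        idx = np.nonzero(above[1:] != above[:-1])[0]
        # compare each detected crossing with the closed-form solar
        # threshold-crossing time at the tag's threshold elevation
        for i in idx[:6]:
            frac = (1.0 - logl[i]) / (logl[i + 1] - logl[i])
            tc = light.index[i] + (light.index[i + 1] - light.index[i]) * frac
            rising = logl[i + 1] > logl[i]
            oracle = solar.crossing_time(tc.normalize(), 10.0, 100.0,
                                         plan.light_threshold_elevation_deg,
                                         rising)
            if oracle is None:
                oracle = solar.crossing_time(
                    (tc - pd.Timedelta(days=1)).normalize(), 10.0, 100.0,
                    plan.light_threshold_elevation_deg, rising)
            err_min = abs((tc - oracle).total_seconds()) / 60.0
            err_min = min(err_min, abs(err_min - 1440.0))
            assert err_min < 2.5

    def test_equatorial_equinox_day_length_near_12h(self):
        plan = SimulationPlan(
            waypoints=[SG, (2.2, 103.73)], stopover_durations_days=[],
            twilight_shading_gamma=(0.0, 0.0),
            initial_residency_days=4.0, final_residency_days=0.5,
            start_time="2019-03-18T00:00:00Z", seed=0)
        track = synthetic.simulate_track(plan)
        light = synthetic.simulate_light(track, plan)
        logl = np.log(light.to_numpy())
        above = logl > 1.0
        idx = np.nonzero(above[1:] != above[:-1])[0]
        rises = [light.index[i] for i in idx if logl[i + 1] > logl[i]]
        sets_ = [light.index[i] for i in idx if logl[i + 1] < logl[i]]
        first_set = next(t for t in sets_ if t > rises[0])
        day_h = (first_set - rises[0]).total_seconds() / 3600.0
        # 12 h plus the twilight widening from the negative threshold angle
        assert day_h == pytest.approx(12.0 + 2 * 3.5 / 15.0, abs=0.25)

    def test_astronomical_night_is_dark_floor(self):
        plan = two_point_plan(twilight_shading_gamma=(0.0, 0.0))
        track = synthetic.simulate_track(plan)
        light = synthetic.simulate_light(track, plan)
        elev = solar.solar_elevation(light.index, 10.0, 100.0)
        dark = light.to_numpy()[np.asarray(elev) < -18.0]
        assert np.allclose(dark, dark.min(), atol=1e-6)
        assert np.log(dark.max()) < 1.0


class TestTemperatureAndWetness:
    def test_altitude_cools_by_lapse_rate(self):
        plan = two_point_plan(flight_altitude_masl=4000.0,
                              initial_residency_days=3.0,
                              final_residency_days=3.0)
        track = synthetic.simulate_track(plan)
        temp = synthetic.simulate_temperature(track, plan, noise_sd_c=0.0)
        sched = plan.schedule()
        flight = [p for p in sched if p["kind"] == "flight"][0]
        ground = temp[temp.index < flight["start"] - pd.Timedelta(hours=4)]
        cruise = temp[(temp.index >= flight["start"] + pd.Timedelta(hours=4))
                      & (temp.index <= flight["end"] - pd.Timedelta(hours=8))]
        drop = ground.mean() - cruise.mean()
        # 6.5 degC/km x 4 km, modulated by the small latitude ramp
        assert drop == pytest.approx(26.0, abs=3.0)

    def test_flight_hours_are_dry_and_counts_capped(self):
        plan = two_point_plan(initial_residency_days=5.0,
                              final_residency_days=5.0)
        track = synthetic.simulate_track(plan)
        wet = synthetic.simulate_wetness(track, plan,
                                         immersion_probability=1.0)
        kinds = synthetic.phase_at(plan, wet.index)
        assert (wet.to_numpy()[kinds == "flight"] == 0).all()
        resident = wet.to_numpy()[kinds == "residency"]
        assert resident.max() == 14
        assert (resident >= 0).all() and (resident <= 14).all()
        # immersion probability 1 -> every clearly pre-departure hour capped
        flight = [p for p in plan.schedule() if p["kind"] == "flight"][0]
        interior = wet[wet.index < flight["start"] - pd.Timedelta(hours=2)]
        assert (interior.to_numpy()[1:] == 14).all()


class TestGrids:
    def test_ridge_crest_and_lowland(self, ridge_dem):
        assert ridge_dem.sample(28.5, 90.0) >= 5000.0
        assert ridge_dem.sample(5.0, 100.0) < 500.0

    def test_inserted_pass_floor(self, ridge_dem):
        assert ridge_dem.sample(28.5, 92.0) == pytest.approx(4720.0, abs=30.0)

    def test_rejects_bad_resolution(self):
        with pytest.raises(ValueError):
            synthetic.make_dem(RidgeSpec(resolution_deg=-0.1))
        with pytest.raises(ValueError):
            synthetic.make_wind_field(WindFieldSpec(resolution_deg=0.0))

    def test_constant_wind_spec_sampled_everywhere(self):
        spec = WindFieldSpec(levels={
            lev: WindLevelSpec(30.0, 0.0, 0.0) for lev in synthetic.LEVELS})
        wf = synthetic.make_wind_field(spec, seed=0)
        for lat, lon in [(0.0, 80.0), (40.0, 100.0), (60.0, 120.0)]:
            u, v = wf.sample("mb850", "2019-06-01T00:00:00Z", lat, lon)
            assert (u, v) == (pytest.approx(30.0), pytest.approx(0.0))

    def test_wind_field_determinism(self):
        spec = WindFieldSpec(levels={
            lev: WindLevelSpec(10.0, 5.0, 8.0) for lev in synthetic.LEVELS})
        a = synthetic.make_wind_field(spec, seed=4)
        b = synthetic.make_wind_field(spec, seed=4)
        assert np.array_equal(a.u["surface"], b.u["surface"])
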