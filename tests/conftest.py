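import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from flyway import geolocation, synthetic

settings.register_profile("default", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("default")

SG = (1.45, 103.73)  # deployment site used across fixtures


@pytest.fixture(scope="session")
def stationary_plan():
    return synthetic.SimulationPlan(
        waypoints=[SG, (2.2, 103.73)],
        stopover_durations_days=[],
        twilight_shading_gamma=(2.0, 0.5),
        initial_residency_days=100.0,
        final_residency_days=1.0,
        start_time="2019-01-01T00:00:00Z",
        seed=3,
    )


@pytest.fixture(scope="session")
def stationary_events(stationary_plan):
    track = synthetic.simulate_track(stationary_plan)
    light = synthetic.simulate_light(track, stationary_plan)
    return geolocation.detect_twilights(light)


@pytest.fixture(scope="session")
def calibration(stationary_events):
    return geolocation.calibrate(stationary_events[:200], *SG)


@pytest.fixture(scope="session")
def ridge_dem():
    return synthetic.make_dem(
        synthetic.RidgeSpec(passes=[(92.0, 4720.0, 0.3)])
    )


@pytest.fixture(scope="session")
def migration_plan():
    """Singapore -> Myanmar coast stopover -> Qinghai-Tibet Plateau."""
    return synthetic.SimulationPlan(
        waypoints=[SG, (16.5, 96.5), (33.0, 92.0)],
        stopover_durations_days=[5.0],
        start_time="2019-04-01T00:00:00Z",
        seed=11,
        initial_residency_days=20.0,
        final_residency_days=10.0,
    )


@pytest.fixture(scope="session")
def migration_truth(migration_plan):
    return synthetic.simulate_track(migration_plan)


@pytest.fixture(scope="session")
def migration_argos(migration_truth, migration_plan):
    return synthetic.degrade_to_argos(migration_truth, migration_plan)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def hours(h):
    return pd.Timedelta(hours=h)
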