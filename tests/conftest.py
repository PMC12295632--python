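import numpy as np
import pytest

from zfpheno import (
    ActivityThresholds,
    CohortDataset,
    Trajectory,
    simulate_cohort,
    standard_schedule,
)


@pytest.fixture(scope="session")
def schedule():
    return standard_schedule(3, 30.0, 30.0)


@pytest.fixture(scope="session")
def thresholds():
    return ActivityThresholds()


@pytest.fixture(scope="session")
def demo_cohort(schedule):
    """Default two-group cohort (12 control + 12 hypokinetic) at 25 Hz."""
    return simulate_cohort(schedule=schedule, seed=1)


def make_trajectory(v_by_interval, rate_hz=10.0, well_id="w1", group="control"):
    """Build a trajectory whose per-interval speeds equal ``v_by_interval``
    exactly (pure x-axis motion)."""
    v = np.asarray(v_by_interval, dtype=float)
    dt = 1.0 / rate_hz
    t = np.arange(len(v) + 1) * dt
    x = np.concatenate([[0.0], np.cumsum(v * dt)])
    y = np.zeros_like(x)
    return Trajectory(well_id=well_id, group=group, rate_hz=rate_hz, t=t, x=x, y=y)


def random_trajectory(rng, n_intervals=200, rate_hz=10.0, scale=1.0, group="control",
                      well_id="w1"):
    dt = 1.0 / rate_hz
    t = np.arange(n_intervals + 1) * dt
    x = np.cumsum(rng.normal(0.0, scale * dt, n_intervals + 1))
    y = np.cumsum(rng.normal(0.0, scale * dt, n_intervals + 1))
    return Trajectory(well_id=well_id, group=group, rate_hz=rate_hz, t=t, x=x, y=y)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
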