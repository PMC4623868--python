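from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from kitetrails import geometry
from kitetrails.telemetry_io import Trajectory

NEST = (57.5, -4.0)


def trajectory_from_km(xy, t_hours, bird_id="bird1", nest=NEST):
    """Build a Trajectory whose projected coordinates are (approximately)
    the given km offsets from the nest, by inverse-projecting them."""
    xy = np.atleast_2d(np.asarray(xy, float))
    lat, lon = geometry.laea_inverse(xy[:, 0], xy[:, 1], nest[0], nest[1])
    t0 = datetime(2021, 6, 1, tzinfo=timezone.utc)
    times = pd.DatetimeIndex([t0 + timedelta(hours=float(h)) for h in t_hours])
    return Trajectory(bird_id=bird_id, times=times, lat=np.asarray(lat), lon=np.asarray(lon))


@pytest.fixture
def km_trajectory():
    return trajectory_from_km


@pytest.fixture(scope="session")
def benchmark_run():
    """One simulated benchmark bird with its fitted analysis (seed 3)."""
    from kitetrails import synthetic
    from kitetrails.model import MovementModel

    traj, truth = synthetic.simulate(synthetic.benchmark_config(), seed=3)
    res = MovementModel(traj).fit()
    return traj, truth, res
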