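from datetime import datetime, timezone

import numpy as np
import pytest

from catmove.tracks_io import Fix, LocalProjection, Trajectory

HOME = (55.70, 12.50)
T0 = datetime(2021, 6, 1, 0, 0, tzinfo=timezone.utc)


def traj_from_local(points, home=HOME, cat_id="t", loc_err_sd=None):
    """Build a Trajectory from (seconds_after_T0, x_m, y_m) triples in the
    local planar frame centred on ``home``."""
    proj = LocalProjection(*home)
    fixes = []
    for dt, x, y in points:
        lat, lon = proj.inverse(np.array([x]), np.array([y]))
        fixes.append(
            Fix(
                time=datetime.fromtimestamp(T0.timestamp() + dt, tz=timezone.utc),
                lat=float(lat[0]),
                lon=float(lon[0]),
                loc_err_sd=loc_err_sd,
            )
        )
    return Trajectory(cat_id=cat_id, fixes=fixes, home=home)


@pytest.fixture
def make_traj():
    return traj_from_local


@pytest.fixture
def home_proj():
    return LocalProjection(*HOME)
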