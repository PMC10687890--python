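import datetime as dt

import numpy as np
import pytest

from contactrsf.landscape import EnvStack, Grid
from contactrsf.tracks import Trajectory

# epoch-aligned base (multiple of any minute interval) so grid anchoring
# in tests is exact
BASE_NS = np.int64(1_577_836_800_000_000_000)  # 2020-01-01T00:00:00Z


def track_from_minutes(minutes, x, y, animal_id="a", **kw) -> Trajectory:
    times = (BASE_NS + (np.asarray(minutes, dtype=float) * 60e9).astype("int64")).astype(
        "datetime64[ns]"
    )
    return Trajectory(animal_id=animal_id, times=times, x=np.asarray(x, float),
                      y=np.asarray(y, float), **kw)


@pytest.fixture(scope="session")
def make_track():
    return track_from_minutes


@pytest.fixture(scope="session")
def tiny_grid() -> Grid:
    return Grid(n_rows=20, n_cols=20, cell_size=30.0, x0=0.0, y_top=600.0)


@pytest.fixture(scope="session")
def tiny_env(tiny_grid) -> EnvStack:
    """Hand-built 20x20 stack with two known days."""
    rng = np.random.default_rng(5)
    n = 20
    road = np.zeros((n, n))
    road[10, :] = 1.0
    wetland = np.zeros((n, n))
    wetland[:5, :5] = 1.0
    water = np.zeros((n, n))
    water[15:18, 15:18] = 1.0
    static = {
        "wetland": wetland,
        "water": water,
        "road": road,
        "fence_or_trail": np.zeros((n, n)),
        "ditch": np.zeros((n, n)),
        "tree_canopy": rng.random((n, n)),
    }
    d0, d1 = dt.date(2020, 1, 1), dt.date(2020, 1, 2)
    food0 = np.zeros((n, n))
    food0[3, 7] = 1.0
    food1 = np.zeros((n, n))
    food1[12, 2] = 1.0
    dynamic = {
        "ndvi": {d0: rng.random((n, n)), d1: rng.random((n, n))},
        "food": {d0: food0, d1: food1},
        "tmax": {d0: np.full((n, n), 21.0), d1: np.full((n, n), 25.0)},
    }
    return EnvStack(grid=tiny_grid, static=static, dynamic=dynamic)
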