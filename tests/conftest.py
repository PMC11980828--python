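import numpy as np
import pytest

from pscore import PoseTrajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_traj(rng):
    """3 frames x 5 heavy atoms, random coordinates near the origin."""
    coords = rng.normal(scale=2.0, size=(3, 5, 3))
    return PoseTrajectory.from_coords(coords, atom_names=list("CNOSC"), frame_dt_ps=20.0)


def make_traj(coords, **kw):
    return PoseTrajectory.from_coords(np.asarray(coords, dtype=float), **kw)
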