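import numpy as np
import pytest

from locusdyn import TwoLocusTrajectory


def make_trajectory(
    pos_a,
    pos_b,
    intensity=None,
    missing=None,
    frame_interval=28.0,
    separation_kb=149.0,
    traj_id="t0",
    states=None,
):
    pos_a = np.asarray(pos_a, dtype=float)
    n = len(pos_a)
    return TwoLocusTrajectory(
        traj_id=traj_id,
        embryo_id="e0",
        separation_kb=separation_kb,
        times=np.arange(n) * frame_interval,
        pos_a=pos_a,
        pos_b=np.asarray(pos_b, dtype=float),
        intensity=np.zeros(n) if intensity is None else np.asarray(intensity, float),
        missing=np.zeros(n, bool) if missing is None else np.asarray(missing, bool),
        frame_interval=frame_interval,
        states=states,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_trajectory():
    """3-frame toy trajectory with one masked frame."""
    pos_a = [[0.0, 0.0, 0.0], [100.0, 0.0, 0.0], [200.0, 50.0, 0.0]]
    pos_b = [[300.0, 0.0, 0.0], [350.0, 0.0, 0.0], [400.0, 0.0, 100.0]]
    intensity = [100.0, 110.0, 95.0]
    return make_trajectory(pos_a, pos_b, intensity=intensity)
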