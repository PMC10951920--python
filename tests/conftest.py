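import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import gliotrack as gt


@pytest.fixture
def simple_trackset() -> gt.TrackSet:
    """Two short tracks, one with a frame gap, in micrometres."""
    t1 = gt.Track("a", frames=np.array([0, 1, 2]), xy=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.5]]))
    t2 = gt.Track("b", frames=np.array([0, 1, 3]), xy=np.array([[5.0, 5.0], [5.5, 5.0], [6.0, 5.5]]))
    return gt.TrackSet([t1, t2], frame_interval=0.03, pixel_size=0.1, cell_id="cell0")


def brownian_trackset(
    D: float,
    n_tracks: int,
    n_frames: int,
    sigma: float = 0.0,
    seed: int = 0,
    dt: float = 0.03,
) -> gt.TrackSet:
    """Pure-Brownian population in a huge arena (no effective boundary)."""
    cfg = gt.SimulationConfig(
        mixture=[(gt.MotionModel("brownian", D=D), 1.0)],
        geometry=gt.Geometry("sheet", radius=200.0),
        localization_sigma=sigma,
        bleach_prob=0.0,
        n_tracks=n_tracks,
        max_frames=n_frames,
        frame_interval=dt,
        seed=seed,
    )
    return gt.simulate_tracks(cfg)


@pytest.fixture
def brownian_factory():
    return brownian_trackset
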