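import numpy as np
import pytest

import rnatraffic as rt


@pytest.fixture(scope="session")
def noiseless_brownian_params():
    """Pure diffusion at typical cytoplasmic mRNP mobility, no localization noise."""
    return rt.MotionParams(diffusion_coefficient=0.1, directed_fraction=0.0,
                           frame_interval=0.15, n_frames=100,
                           localization_noise=0.0)


@pytest.fixture(scope="session")
def noiseless_directed_params():
    """A straight constant-speed run at motor speed, no jitter or noise."""
    return rt.MotionParams(directed_speed=2.6, direction_jitter=0.0,
                           frame_interval=1.0 / 7.36, n_frames=63,
                           localization_noise=0.0)


@pytest.fixture(scope="session")
def geometry():
    return rt.make_cell_geometry(width_px=200, height_px=200, pixel_size=0.1,
                                 nucleus_radius_fraction=0.3, irregularity=0.15,
                                 seed=11)


@pytest.fixture(scope="session")
def brownian_ensemble(noiseless_brownian_params):
    """500 seeded Brownian tracks for ensemble-statistics checks."""
    return [rt.simulate_brownian_track(noiseless_brownian_params, seed=s, track_id=s)
            for s in range(500)]
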