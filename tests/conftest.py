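import numpy as np
import pytest

from mecopto import synthdata as sd


@pytest.fixture(scope="session")
def traj600():
    """Long foraging trajectory shared by the expensive statistical tests."""
    return sd.simulate_trajectory(600.0, seed=1)


@pytest.fixture(scope="session")
def traj120():
    return sd.simulate_trajectory(120.0, seed=2)


@pytest.fixture(scope="session")
def stim8():
    return sd.generate_stim_train(8.0, 10.0, 600.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid_cell():
    return sd.GroundTruthCell(
        "g0",
        "grid",
        peak_rate_hz=25.0,
        grid_spacing_cm=40.0,
        grid_orientation_deg=10.0,
        grid_phase_cm=(7.0, 13.0),
    )


@pytest.fixture(scope="session")
def grid_spikes(grid_cell, traj600):
    return sd.generate_spikes(sd.rate_function(grid_cell), traj600, seed=3)


def make_day(cells, duration_s=240.0, seed=0, **kwargs):
    """Small synthetic day for integration-style tests."""
    from mecopto import session_io as sio

    cfg = sd.SessionConfig(cells=cells, duration_s=duration_s, **kwargs)
    bundles, manifest = sd.generate_session(cfg, seed=seed)
    return sio.validate_day(bundles), manifest
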