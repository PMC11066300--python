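import numpy as np
import pytest

from sptpalm import ParameterSet, calibrate_camera, filter_localizations, localize_stack
from sptpalm.simulate import SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return ParameterSet()


@pytest.fixture(scope="session")
def small_movie():
    """A short sparse movie with ground truth, shared across tests."""
    cfg = SimulationConfig(n_frames=400, n_molecules=220, n_dark_frames=120, rng_seed=42)
    movie, dark, gt = simulate(cfg)
    return cfg, movie, dark, gt


@pytest.fixture(scope="session")
def small_movie_localized(small_movie):
    cfg, movie, dark, gt = small_movie
    params = ParameterSet()
    calib = calibrate_camera(dark, params.camera.e_per_adu, params.camera.qe)
    locs = localize_stack(movie, calib, params)
    filtered, counts = filter_localizations(locs, params.filter)
    return cfg, gt, params, locs, filtered
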