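import numpy as np
import pytest

from marshagb import RasterGrid, SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_grid():
    return RasterGrid(nrows=10, ncols=12, origin_x=1000.0, origin_y=5000.0,
                      pixel_size=250.0)


@pytest.fixture(scope="session")
def default_scene():
    """A small scene at the default noise levels, shared across tests."""
    cfg = SceneConfig(nrows=30, ncols=30, seed=11)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def noise_free_scene():
    cfg = SceneConfig(nrows=30, ncols=30, ndvi_noise_sd=0.0, agb_noise_cv=0.0,
                      seed=5)
    return generate_scene(cfg)
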