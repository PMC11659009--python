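import numpy as np
import pytest

from canopyagb.geo import Affine, RasterGrid
from canopyagb.scene import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """Default 30-plot bolting scene, shared read-only across tests."""
    return generate_scene(SceneConfig(seed=11))


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free deterministic scene (closed-form generator checks)."""
    cfg = SceneConfig(seed=5, noise_sd_reflectance=0.0, noise_sd_height=0.0,
                      agb_cv=0.0, soil_brightness_cv=0.0, veg_jitter_cv=0.0,
                      ph_cv=0.0, cover_logit_sd=0.0)
    return generate_scene(cfg)


@pytest.fixture
def unit_grid():
    """10x10 raster on a 1 m grid with origin at (0, 10), north-up."""
    return RasterGrid(values=np.zeros((10, 10)),
                      transform=Affine(1, 0, 0, 0, -1, 10))
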