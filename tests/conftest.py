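import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from fcquant.image import RasterImage
from fcquant.synthetic import SceneSpec, control_spec, generate_scene


@pytest.fixture(scope="session")
def small_scene_spec() -> SceneSpec:
    """A reduced control scene (~20 contacts) that still exercises the full
    detection chain quickly."""
    return control_spec(
        image_size=(256, 256),
        cell_radius_um=20.0,
        fa_count_law=(20.0, 0.0),
        rng_seed=7,
    )

@pytest.fixture(scope="session")
def small_scene(small_scene_spec):
    return generate_scene(small_scene_spec)


@pytest.fixture(scope="session")
def default_scene():
    """One full-size control scene at the study conditions."""
    return generate_scene(control_spec(rng_seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def as_image(pixels, pixel_size_um=0.2, name="test") -> RasterImage:
    return RasterImage(np.asarray(pixels, dtype=np.float64), pixel_size_um, name)
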