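import numpy as np
import pytest

from desertfvc.synthetic import SceneSpec, generate_scene, sample_rois


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """A small random RGB image exercising the full intensity range."""
    return rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)


@pytest.fixture(scope="session")
def small_scene():
    """A 192x192 scene at 30% cover with well-separated palettes."""
    return generate_scene(SceneSpec(target_fvc=30.0, height=192, width=192, seed=42))


@pytest.fixture(scope="session")
def small_scene_rois(small_scene):
    return sample_rois(small_scene, seed=7)
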