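import numpy as np
import pytest

from cryoloc import phantom as ph


@pytest.fixture(scope="session")
def views_256():
    return ph.default_views((256, 256))


@pytest.fixture(scope="session")
def clean_config_256():
    """Clean rendering conditions: no clutter, mild noise."""
    return ph.PhantomConfig(image_size_px=(256, 256), noise_sigma=2.0, clutter_count=0,
                            contrast_blob_probability=0.0)


@pytest.fixture(scope="session")
def clean_scene(views_256, clean_config_256):
    return ph.sample_scene(clean_config_256, ph.BalloonModel(), views_256, rng_seed=7)


@pytest.fixture(scope="session")
def clean_frame(clean_scene, views_256, clean_config_256):
    """One rendered clean frontal frame with its truth attached."""
    img = ph.render_view(clean_scene, views_256[0], clean_config_256)
    return img, clean_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
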