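import numpy as np
import pytest

from daphtrack import SceneParams, generate_video


@pytest.fixture(scope="session")
def small_scene_params():
    """A compact clean scene: 3 animals, no nuisance objects, no pixel noise."""
    return SceneParams(
        width=160,
        height=120,
        n_frames=60,
        n_daphnia=3,
        n_noise_static=0,
        n_noise_drift=0,
        pixel_noise_sigma=0.0,
        blob_axis_range=(3.0, 5.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_params):
    return generate_video(small_scene_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
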