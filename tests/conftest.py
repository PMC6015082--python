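import numpy as np
import pytest

from endopolar import SceneParams, generate_scene, render_movie


@pytest.fixture(scope="session")
def small_scene():
    """A small rendered control scene shared by segmentation/detection tests."""
    params = SceneParams(
        n_cells=3,
        n_frames=8,
        image_shape=(512, 512),
        endosome_radius_range=(4.0, 14.0),
        deformed_fraction=0.0,
        seed=42,
    )
    truth = generate_scene(params)
    stack, sidecar = render_movie(truth, channels=("nucleus", "endosomes"))
    return params, truth, stack, sidecar


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
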