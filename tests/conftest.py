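import numpy as np
import pytest

from leukoseg import SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(0xC0FFEE)


def random_binary_mask(rng, shape=(40, 40), p=0.35):
    return (rng.random(shape) < p).astype(np.uint8)


@pytest.fixture(scope="session")
def small_scene():
    """A modest scene shared by read-only tests (do not mutate)."""
    params = SceneParams(
        width=512, height=384,
        n_leukocytes=3, lobe_count_range=(1, 4),
        n_platelets=8, n_stains=2, n_erythrocytes=12, n_artifacts=1,
        seed=11,
    )
    img, truth = generate_scene(params)
    return params, img, truth
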