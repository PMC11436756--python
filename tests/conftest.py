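import numpy as np
import pytest
from hypothesis import settings

from acquant import KineticConfig, SceneConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def noiseless_scene_cfg():
    """Default geometry, no camera noise: exact pixel statistics."""
    return SceneConfig(poisson_on=False, gaussian_sd=0.0, seed=7)


@pytest.fixture
def uniform_scene_cfg():
    """All enrichment factors 1: the AC channel is flat over the cell."""
    return SceneConfig(
        cilium_factor=1.0,
        endosome_factor=1.0,
        plasma_membrane_factor=1.0,
        poisson_on=False,
        gaussian_sd=0.0,
        seed=7,
    )


@pytest.fixture
def noiseless_kinetics():
    return KineticConfig(noise_sd=0.0, seed=7)


def random_masks(rng, n=20, shape=(24, 24), density=0.25):
    """Randomized binary fixtures shared by several oracle-equivalence tests."""
    return [rng.random(shape) < density for _ in range(n)]
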