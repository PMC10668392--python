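import numpy as np
import pytest

from phenotherm.synthetic_scene import GenotypeParams, SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small but complete two-genotype experiment for fast tests."""
    return SceneConfig(
        random_seed=7,
        n_plants=4,
        n_days=6,
        genotypes=[GenotypeParams("B104"), GenotypeParams("H99", g_max=0.30)],
    )
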