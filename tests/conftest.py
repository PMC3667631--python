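import numpy as np
import pytest

from platescreen import EffectModel, ScreenDesign, simulate_screen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    return ScreenDesign(n_genes=200, seed=7)


@pytest.fixture
def noise_only_effects():
    return EffectModel(
        plate_effect_sd=0.0, row_effect_sd=0.0, col_effect_sd=0.0, noise_cv=0.05
    )


@pytest.fixture
def small_screen(small_design, noise_only_effects):
    return simulate_screen(small_design, noise_only_effects)


def random_plate(rng, loc=1000.0, scale=100.0):
    """A generic full 8x12 plate matrix of positive signals."""
    return rng.normal(loc, scale, size=(8, 12))
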