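import numpy as np
import pytest

from dabquant import SynthConfig, generate_core


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A 100x117 random RGB image (dimensions not divisible by 8)."""
    return rng.integers(0, 256, (100, 117, 3)).astype(np.uint8)


@pytest.fixture
def white_image():
    return np.full((80, 80, 3), 255, dtype=np.uint8)


@pytest.fixture(scope="session")
def synthetic_core():
    """A mid-sized synthetic core with strong DAB and its ground truth."""
    cfg = SynthConfig(height=160, width=160, tissue_fraction=0.8,
                      dab_fraction_of_tissue=0.5, dab_level="high",
                      noise_sd=0.02, seed=7)
    return generate_core(cfg)
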