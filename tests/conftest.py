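import numpy as np
import pytest

from cdsfcrf import generate_phantom, add_texture


@pytest.fixture(scope="session")
def small_phantom():
    """64x64 textured phantom at 1 mm/pixel (the 50x45 mm prostate fits)."""
    ph = generate_phantom(64, 64, n_lesions=2, pixel_size_mm=1.0, seed=7)
    return add_texture(ph, 0.15, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
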