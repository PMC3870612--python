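import numpy as np
import pytest

from waveclear import ImageGrid, PhantomSpec, add_gaussian_noise, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """64x64 8-bit phantom with one known step edge."""
    return generate_phantom(PhantomSpec(rows=64, cols=64, seed=7))


@pytest.fixture
def noisy_pair():
    """(clean, noisy) 128x128 phantom pair at the default noise level."""
    clean = generate_phantom(PhantomSpec(rows=128, cols=128, seed=11))
    noisy = add_gaussian_noise(clean, sigma=0.01, seed=13)
    return clean, noisy


@pytest.fixture
def random_image(rng):
    return ImageGrid(rng.uniform(0, 255, size=(32, 32)), bit_depth=8)
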