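import numpy as np
import pytest

from cuffseg.phantom import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_easy_dataset():
    """12 small, high-contrast, noiseless phantoms (4 subjects x 3 slices)."""
    cfg = PhantomConfig(image_size=64, contrast=255, noise_sigma=0,
                        slices_per_subject=(3, 3), seed=11)
    return generate_dataset(cfg, 4)


@pytest.fixture(scope="session")
def default_small_dataset():
    """Default-difficulty phantoms at test resolution (6 subjects)."""
    cfg = PhantomConfig(image_size=64, slices_per_subject=(3, 3), seed=5)
    return generate_dataset(cfg, 6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
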