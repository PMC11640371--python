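import numpy as np
import pytest

from cadeye.synthetic import GeneratorParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """One seeded random RGB image."""
    return rng.integers(0, 256, size=(40, 56, 3), dtype=np.uint8)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small on-disk synthetic dataset shared by tests that need files.

    Low raw resolution keeps generation fast; the images still carry the full
    class signatures.
    """
    root = tmp_path_factory.mktemp("tiny_ds")
    params = GeneratorParams(raw_height=96, raw_width=96, n_per_class=6,
                             seed=42, test_fraction=0.2)
    manifest = generate_dataset(params, root)
    return manifest, params, root
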