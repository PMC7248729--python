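import numpy as np
import pytest

from stooltrait.synthetic_data import GeneratorConfig, generate_image


@pytest.fixture(scope="session")
def gen_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def paste_sample(gen_cfg):
    """One deterministic synthetic 'paste' image with its ground-truth mask."""
    return generate_image("paste", gen_cfg, seed=3)


@pytest.fixture(scope="session")
def dim_sample(gen_cfg):
    """A darkened synthetic image with headroom: no channel exceeds 255/1.5.

    Round-trip illumination tests need scaling up to k = 1.5 without
    clipping, so the base image is pre-scaled down.
    """
    from stooltrait.illumination import simulate_illumination

    img, mask = generate_image("paste", gen_cfg, seed=7)
    return simulate_illumination(img, 0.6), mask


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
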