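import numpy as np
import pytest

from msgan.discriminator import DiscriminatorConfig, build_patch_discriminator
from msgan.generator import GeneratorConfig, build_generator
from msgan.phantoms import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(canvas_side=32, seed=7)


@pytest.fixture(scope="session")
def phantom_dataset(phantom_spec):
    return generate_dataset(phantom_spec, 6)


@pytest.fixture
def tiny_gen_config():
    return GeneratorConfig(base_channels=4)


@pytest.fixture
def tiny_generator(tiny_gen_config):
    return build_generator(tiny_gen_config, seed=3)


@pytest.fixture
def tiny_discriminator():
    return build_patch_discriminator(DiscriminatorConfig(base_channels=4), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
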