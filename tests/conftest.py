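import numpy as np
import pytest
from hypothesis import settings

from cpblend.fixtures import FixtureConfig, make_source_dataset
from cpblend.gan import GanConfig, train_dcgan

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return FixtureConfig(image_size=96, n_images=3)


@pytest.fixture(scope="session")
def tiny_dataset(small_config):
    """A 3-image labeled fixture dataset plus its 20-sprite pool."""
    return make_source_dataset(small_config)


@pytest.fixture(scope="session")
def trained_gan():
    """One shared adversarial training run on a 20-sprite pool.

    30 epochs at batch size 8 — enough for the generator to produce
    segmentable foregrounds and the discriminator to separate real patches
    from noise.  Returns (generator, discriminator, pool, elapsed_seconds).
    """
    import time

    _, pool = make_source_dataset(FixtureConfig(image_size=96, n_images=2))
    config = GanConfig(epochs=30, batch_size=8, seed=1)
    t0 = time.time()
    gen, disc = train_dcgan(pool, config, return_discriminator=True)
    elapsed = time.time() - t0
    return gen, disc, pool, elapsed
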