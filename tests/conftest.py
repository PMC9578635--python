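import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mofaug import PhantomSpec, generate_phantom

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: small, fast phantom parameters used throughout the suite
SMALL_PHANTOM = dict(
    image_size=128,
    n_lesions=3,
    lesion_radius_range=(3.0, 8.0),
    noise_sd=5.0,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """A 128x128 phantom triplet: (ImageSlice[HU], organ mask, label)."""
    return generate_phantom(PhantomSpec(seed=7, **SMALL_PHANTOM))


@pytest.fixture
def phantom_spec():
    def make(seed):
        return PhantomSpec(seed=seed, **SMALL_PHANTOM)

    return make
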