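import numpy as np
import pytest

from vmseg import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_sample():
    """One default-size phantom shared by read-only tests."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def small_phantom():
    """A quarter-size phantom for pipeline tests that re-run segment()."""
    return generate_phantom(
        PhantomConfig(size=256, patch_radius_range=(20.0, 35.0), seed=2)
    )
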