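import numpy as np
import pytest

from ventrecon.phantom import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom32():
    """Desk-scale breathing phantom shared across read-only tests."""
    return build_phantom(PhantomSpec(grid_size=32, seed=7))


@pytest.fixture(scope="session")
def smooth_volume():
    """A smooth positive test image for registration/filtering tests."""
    from scipy.ndimage import gaussian_filter
    g = np.random.default_rng(5).normal(size=(32, 32, 32))
    v = gaussian_filter(g, 3.0)
    return v - v.min() + 0.1
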