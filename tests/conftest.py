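import numpy as np
import pytest

from copesets import DesignSpec, fit_glm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_fit(rng):
    """A one-sample GLM fit on a noisy 12x12 blob, reused across tests."""
    shape = (12, 12)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mu = 3.0 * (np.hypot(yy - 5.5, xx - 5.5) < 4)
    data = mu[None] + rng.standard_normal((20, *shape))
    return mu, fit_glm(data, DesignSpec.one_sample(20))
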