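import numpy as np
import pytest

from gleam.glm_core import TraitVector, build_design


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def gaussian_toy():
    """Small gaussian instance with a planted ancestry effect + covariate."""
    rng = np.random.default_rng(7)
    I = 150
    S = rng.binomial(2, 0.8, size=I).astype(float)
    E = rng.standard_normal(I)
    y = 0.4 * S + 0.6 * E + rng.standard_normal(I)
    return TraitVector(y, "gaussian"), build_design(S, E), S, E


def random_gaussian_instance(rng, I=120, p=1, effect=0.5):
    """A random gaussian fit instance for closed-form-vs-oracle checks."""
    S = rng.binomial(2, rng.uniform(0.6, 0.9), size=(I, p)).astype(float)
    E = rng.standard_normal((I, 1))
    beta = rng.normal(0, effect, size=p)
    y = S @ beta + 0.5 * E[:, 0] + rng.standard_normal(I)
    return TraitVector(y, "gaussian"), build_design(S, E)
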