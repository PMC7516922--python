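import numpy as np
import pytest

from afcorr import PairedSample, RelationshipSpec, generate_relationship


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def linear_grid():
    """Noiseless y = 1 + x on an even grid of 100 points in [0, 1]."""
    return generate_relationship(RelationshipSpec("linear", n=100))


@pytest.fixture
def quartic_grid():
    """Noiseless y = x^4 on an even grid of 100 points in [-1, 1]."""
    return generate_relationship(RelationshipSpec("poly4", n=100))


@pytest.fixture
def exponential_grid():
    """Noiseless y = exp(0.05 x) on an even grid of 100 points in [0, 100]."""
    return generate_relationship(RelationshipSpec("exponential", n=100))


@pytest.fixture
def parabola_grid():
    """Noiseless y = 4 (x - 0.5)^2 on an even grid of 100 points in [0, 1]."""
    return generate_relationship(RelationshipSpec("parabolic", n=100))


def random_circle(n, seed):
    """Uniformly sampled points on the unit circle."""
    return generate_relationship(
        RelationshipSpec("circular", n=n, x_design="uniform_random"), seed=seed
    )


def fuzz_sample(rng, n=None):
    """A random bivariate sample mixing noisy functional and independent data."""
    if n is None:
        n = int(rng.integers(20, 120))
    x = rng.standard_normal(n)
    kind = int(rng.integers(0, 4))
    if kind == 0:
        y = rng.standard_normal(n)
    elif kind == 1:
        y = np.exp(x) + 0.3 * rng.standard_normal(n)
    elif kind == 2:
        y = x**2 + 0.2 * rng.standard_normal(n)
    else:
        y = np.sin(2 * x) + 0.1 * rng.standard_normal(n)
    return PairedSample(x, y)
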