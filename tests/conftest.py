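import numpy as np
import pytest

from deepvis import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """Tiny nonnegative count matrix with ids."""
    vals = rng.poisson(2.0, size=(12, 7)).astype(float)
    return ExpressionMatrix(vals, [f"g{j}" for j in range(7)],
                            [f"c{i}" for i in range(12)])


def random_ball_points(rng, n, dim=2, rmax=0.95):
    """Uniform-ish points strictly inside the unit Poincaré ball."""
    v = rng.normal(size=(n, dim))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rmax * rng.random(n) ** (1.0 / dim)
    return v * r[:, None]


def random_hyperboloid_points(rng, n, dim=2, scale=1.5):
    """Points on the unit hyperboloid ⟨x,x⟩_L = −1, x₀ > 0."""
    sp = scale * rng.normal(size=(n, dim))
    x0 = np.sqrt(1.0 + np.sum(sp * sp, axis=1, keepdims=True))
    return np.hstack([x0, sp])
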