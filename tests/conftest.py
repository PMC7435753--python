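import numpy as np
import pytest

from nodulecascade.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def default_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def sample(default_params):
    """One deterministic phantom with nodules, vessels and distractors."""
    return generate_phantom(default_params, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g
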