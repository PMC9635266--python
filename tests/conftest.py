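import numpy as np
import pytest

from recurlang.codebooks import default_codebooks
from recurlang.examples import (ball_excerpt, frog_excerpt, ice_cream_excerpt,
                                jump_excerpt)


@pytest.fixture(scope="session")
def codebooks():
    return default_codebooks()


@pytest.fixture(scope="session")
def frog():
    return frog_excerpt()


@pytest.fixture(scope="session")
def ball():
    return ball_excerpt()


@pytest.fixture(scope="session")
def ice_cream():
    return ice_cream_excerpt()


@pytest.fixture(scope="session")
def jump():
    return jump_excerpt()


def random_series(rng: np.random.Generator, n: int, n_symbols: int = 5,
                  mask_prob: float = 0.2) -> np.ndarray:
    """A random categorical series with some uniquely-masked positions."""
    s = rng.integers(1, n_symbols + 1, size=n).astype(np.int64)
    mask = rng.random(n) < mask_prob
    s[mask] = -(np.arange(mask.sum()) + 1)
    return s
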