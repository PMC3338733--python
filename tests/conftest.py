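import numpy as np
import pytest

from metachain import (
    SiteAtlas,
    SiteDistribution,
    TransitionMatrix,
    load_fixtures,
)


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def atlas2():
    return SiteAtlas(("alpha", "beta"))


@pytest.fixture(scope="session")
def atlas3():
    return SiteAtlas(("alpha", "beta", "gamma"))


@pytest.fixture(scope="session")
def atlas50():
    return SiteAtlas.numbered(50)


@pytest.fixture
def swap_chain(atlas2):
    """Period-2 deterministic chain: 1 <-> 2."""
    return TransitionMatrix(atlas2, np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def cycle3(atlas3):
    """Deterministic directed cycle 1 -> 2 -> 3 -> 1."""
    return TransitionMatrix(
        atlas3, np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    )


def random_chain(n: int, seed: int, strictly_positive: bool = True):
    """Random row-stochastic matrix on a numbered atlas (test helper)."""
    rng = np.random.default_rng(seed)
    a = rng.random((n, n)) + (0.05 if strictly_positive else 0.0)
    a /= a.sum(axis=1, keepdims=True)
    return TransitionMatrix(SiteAtlas.numbered(n), a)


def dist(atlas: SiteAtlas, *probs: float) -> SiteDistribution:
    return SiteDistribution(atlas, np.array(probs, dtype=float))
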