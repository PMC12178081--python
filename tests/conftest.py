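"""Shared fixtures: small deterministic datasets and trees."""

import numpy as np
import pytest

from morphokit.geometry import ShapeMatrix
from morphokit.ordination import Phylogeny


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_pair(rng):
    a = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])
    b = np.array([[0.0, 0.1], [1.2, -0.1], [0.5, 0.9]])
    return a, b


@pytest.fixture
def toy_shapes(rng):
    """8 observations by 6 shape variables with a dominant direction."""
    v = rng.normal(size=6)
    v /= np.linalg.norm(v)
    X = 0.4 * np.outer(rng.normal(size=8), v) + \
        0.05 * rng.normal(size=(8, 6)) + 1.0
    return ShapeMatrix(X, kind="landmarks2d", k=3, m=2)


@pytest.fixture
def allometric_shapes(rng):
    """Noise-free shapes lying exactly on an allometric line."""
    n, p = 30, 10
    size = rng.uniform(1.0, 3.0, n)
    v = rng.normal(size=p)
    v /= np.linalg.norm(v)
    X = 0.5 + np.outer(size, v) * 0.2
    sm = ShapeMatrix(X, kind="landmarks2d", k=5, m=2)
    return sm, size, v


@pytest.fixture
def balanced_tree4():
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def random_tree5():
    return Phylogeny.from_newick(
        "((A:0.7,(B:0.3,C:0.4):0.5):0.6,(D:1.1,E:0.9):0.4);")


@pytest.fixture
def star_tree5():
    return Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")
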