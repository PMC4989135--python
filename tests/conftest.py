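import numpy as np
import pytest

from hicats import Country, GeneDataset


class StubEvaluator:
    """Evaluator with an arbitrary fitness function of the bit vector.

    Mirrors the SubsetEvaluator surface used by the search operators
    (``evaluate``, ``n_fits``, ``best``) without touching a classifier,
    so landscape-dependent behaviour can be tested against brute force.
    """

    def __init__(self, fn):
        self.fn = fn
        self.n_fits = 0
        self.best = None

    def evaluate(self, country, weights=None):
        self.n_fits += 1
        country.fitness = float(self.fn(country.bits))
        country.accuracy = min(max(country.fitness, 0.0), 1.0)
        if self.best is None or country.fitness > self.best.fitness:
            self.best = country.copy()
        return country


@pytest.fixture
def stub_evaluator():
    return StubEvaluator


@pytest.fixture
def separable_two_class():
    """Six samples, one gene, classes separated by sign."""
    X = np.array([[-5.0], [-4.0], [-6.0], [5.0], [4.0], [6.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    return GeneDataset(X, y)


@pytest.fixture
def separable_ten_gene():
    """Ten genes, only gene 1 informative, two well-separated classes."""
    rng = np.random.default_rng(7)
    X = rng.normal(0.0, 1.0, size=(12, 10))
    y = np.repeat([0, 1], 6)
    X[:, 0] += y * 10.0
    return GeneDataset(X, y)


def country_of(indices, n):
    """Country selecting the given 1-based gene positions."""
    bits = np.zeros(n, dtype=np.uint8)
    for i in indices:
        bits[i - 1] = 1
    return Country(bits)


@pytest.fixture
def make_country():
    return country_of
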