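import numpy as np
import pytest

from ncgex.graph import BinaryGeneGraph, WeightedGeneGraph
from ncgex.simulate import generate_random_graph


@pytest.fixture
def triangle_graph() -> WeightedGeneGraph:
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 150
    w[0, 2] = w[2, 0] = 100
    w[1, 2] = w[2, 1] = 200
    return WeightedGeneGraph(["a", "b", "c"], w)


@pytest.fixture
def path_graph() -> BinaryGeneGraph:
    """3-node path 0-1-2."""
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return BinaryGeneGraph(["g1", "g2", "g3"], adj)


def random_binary_graph(d: int, p: float, seed: int) -> BinaryGeneGraph:
    return generate_random_graph(d, p, seed=seed)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
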