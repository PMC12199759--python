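import random

import numpy as np
import pytest

from growperc import NetworkGraph

from oracles import random_digraph_edges


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pyrng():
    return random.Random(987)


def make_random_digraph(n: int, p: float, pyrng: random.Random):
    """A random simple digraph plus its raw edge list (for the oracles)."""
    edges = random_digraph_edges(n, p, pyrng)
    return NetworkGraph(n, directed=True, edges=edges), edges


def random_states(n: int, q: float, pyrng: random.Random):
    return np.array([1 if pyrng.random() < q else 0 for _ in range(n)], dtype=np.int8)
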