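"""Small worked-example networks used in docs, tests, and demos."""

from __future__ import annotations

import numpy as np

from .netgen import NetworkGraph

__all__ = ["make_fig1a_fixture", "make_cascade_fixture"]


def make_fig1a_fixture() -> tuple[NetworkGraph, np.ndarray, int]:
    """Eight-node directed worked example for the induced index.

    The focal node 0 is inactive with two active in-neighbors: node 1
    (which itself has three active in-neighbors 3, 4, 5) and node 2
    (with two active in-neighbors 6, 7).  The induced index of node 0 is
    therefore max{3, 2} = 3: it activates for any threshold m ≤ 3.

    Returns (graph, states, focal_node).
    """
    edges = [(1, 0), (2, 0), (3, 1), (4, 1), (5, 1), (6, 2), (7, 2)]
    graph = NetworkGraph(8, directed=True, edges=edges)
    states = np.array([0, 1, 1, 1, 1, 1, 1, 1], dtype=np.int8)
    return graph, states, 0


def make_cascade_fixture() -> tuple[NetworkGraph, np.ndarray, np.ndarray]:
    """A five-node directed graph whose m=2 growth cascade takes two sweeps.

    Seeds are nodes 0, 1, 2.  Node 1 has the two active in-neighbors 0 and
    2, so it induces node 3 in the first sweep.  Node 3's own in-neighbors
    0 and 1 are active, so once node 3 is active it induces node 4 in the
    second sweep — an activation enabled only by the first one.  The
    expected fixed point (all five nodes active) is stated by hand, not
    recomputed, so tests can hold the engine against it.

    Returns (graph, initial_states, expected_final_states) for m=2.
    """
    edges = [(0, 1), (2, 1), (0, 3), (1, 3), (3, 4)]
    graph = NetworkGraph(5, directed=True, edges=edges)
    init = np.array([1, 1, 1, 0, 0], dtype=np.int8)
    expected = np.ones(5, dtype=np.int8)
    return graph, init, expected
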