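"""Cascade dynamics and giant-component measurement on concrete graphs.

The growth cascade activates an inactive node i as soon as some active
in-neighbor j of i itself has at least m active in-neighbors (the *induced
index* of i, the maximum such count over i's active in-neighbors, reaches
m).  The dynamics are monotone, so the final state is the unique least
fixed point above the initial seeds, independent of update order; the
implementation sweeps synchronously with sparse matrix-vector products.

The retention cascade is the mirror process: all nodes start active, a
distinguished *pinned* set never deactivates, and every other node is
deactivated while it lacks the same induced-index support; this converges
to the greatest fixed point with the pinned set held at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Callable, Iterable, Optional

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .netgen import NetworkGraph

__all__ = [
    "GrowthParams",
    "CascadeResult",
    "ComponentReport",
    "EnsembleSummary",
    "seed_states",
    "induced_index",
    "run_growth",
    "run_retention",
    "components_active",
    "simulate_ensemble",
    "write_states",
    "read_states",
]


@dataclass(frozen=True)
class GrowthParams:
    """Cascade parameters: initial active probability q and threshold m."""

    q: float
    m: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if self.m < 0:
            raise ValueError("m must be non-negative")


@dataclass(frozen=True)
class CascadeResult:
    final_states: np.ndarray
    active_fraction: float
    sweeps: int
    activated_order: np.ndarray  # nodes activated (growth) / deactivated (retention)


@dataclass(frozen=True)
class ComponentReport:
    """Giant components of the active subgraph.

    Undirected graphs report the largest connected component (GCC); the
    directed bow-tie reports the largest strongly connected component
    (GSCC) and GOUT = GSCC plus everything reachable from it.
    """

    directed: bool
    gcc_nodes: int = 0
    gscc_nodes: int = 0
    gout_nodes: int = 0
    n: int = 0
    giant_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        count = self.gout_nodes if self.directed else self.gcc_nodes
        object.__setattr__(self, "giant_fraction", count / self.n if self.n else 0.0)


def _validate_states(graph: NetworkGraph, states: np.ndarray) -> np.ndarray:
    states = np.asarray(states)
    if states.shape != (graph.n,):
        raise ValueError(f"states must have length n={graph.n}")
    if not np.isin(states, (0, 1)).all():
        raise ValueError("states must be binary")
    return states.astype(bool)


def _forward_matrix(graph: NetworkGraph) -> sparse.csr_matrix:
    """CSR matrix A with A[u, v] = 1 for each edge u→v (both ways if undirected)."""
    src, dst = graph.edge_arrays()
    if not graph.directed:
        src, dst = np.concatenate([src, dst]), np.concatenate([dst, src])
    data = np.ones(src.shape[0], dtype=np.int64)
    return sparse.csr_matrix((data, (src, dst)), shape=(graph.n, graph.n))


def seed_states(graph: NetworkGraph, q: float, seed: int) -> np.ndarray:
    """Independently activate each node with probability q (reproducible)."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random(graph.n) < q).astype(np.int8)


def induced_index(graph: NetworkGraph, states: np.ndarray, node: int) -> Optional[int]:
    """Induced index of ``node``: max over its active in-neighbors j of j's
    active in-neighbor count; ``None`` when no in-neighbor is active
    (activation is then impossible for any threshold)."""
    if not 0 <= node < graph.n:
        raise ValueError(f"node {node} out of range")
    s = _validate_states(graph, states)
    best: Optional[int] = None
    for j in graph.in_adjacency[node]:
        if s[j]:
            count = int(s[graph.in_adjacency[j]].sum())
            best = count if best is None else max(best, count)
    return best


def run_growth(graph: NetworkGraph, init: np.ndarray, m: int) -> CascadeResult:
    """Iterate growth activations to the least fixed point above ``init``."""
    if m < 0:
        raise ValueError("m must be non-negative")
    active = _validate_states(graph, init)
    A = _forward_matrix(graph)
    order: list[np.ndarray] = []
    sweeps = 0
    while True:
        in_count = active.astype(np.int64) @ A  # active in-neighbor counts
        inducer = active & (in_count >= m)
        supported = (inducer.astype(np.int64) @ A) > 0
        fresh = supported & ~active
        if not fresh.any():
            break
        active |= fresh
        order.append(np.flatnonzero(fresh))
        sweeps += 1
    activated = np.concatenate(order) if order else np.empty(0, dtype=np.int64)
    return CascadeResult(
        final_states=active.astype(np.int8),
        active_fraction=float(active.sum() / graph.n) if graph.n else 0.0,
        sweeps=sweeps,
        activated_order=activated,
    )


def run_retention(graph: NetworkGraph, pinned: Iterable[int], m: int) -> CascadeResult:
    """Deactivate unsupported non-pinned nodes down to the greatest fixed point.

    All nodes start active; a node is retained while some in-neighbor j is
    active with at least m active in-neighbors, or it is pinned.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    pinned_mask = np.zeros(graph.n, dtype=bool)
    pinned_idx = np.fromiter((int(p) for p in pinned), dtype=np.int64)
    if pinned_idx.size and (pinned_idx.min() < 0 or pinned_idx.max() >= graph.n):
        raise ValueError("pinned node out of range")
    pinned_mask[pinned_idx] = True
    active = np.ones(graph.n, dtype=bool)
    A = _forward_matrix(graph)
    order: list[np.ndarray] = []
    sweeps = 0
    while True:
        in_count = active.astype(np.int64) @ A
        inducer = active & (in_count >= m)
        supported = (inducer.astype(np.int64) @ A) > 0
        drop = active & ~pinned_mask & ~supported
        if not drop.any():
            break
        active &= ~drop
        order.append(np.flatnonzero(drop))
        sweeps += 1
    deactivated = np.concatenate(order) if order else np.empty(0, dtype=np.int64)
    return CascadeResult(
        final_states=active.astype(np.int8),
        active_fraction=float(active.sum() / graph.n) if graph.n else 0.0,
        sweeps=sweeps,
        activated_order=deactivated,
    )


def components_active(graph: NetworkGraph, states: np.ndarray) -> ComponentReport:
    """Giant component(s) of the subgraph induced by active nodes."""
    active = _validate_states(graph, states)
    n_active = int(active.sum())
    if n_active == 0:
        return ComponentReport(directed=graph.directed, n=graph.n)
    src, dst = graph.edge_arrays()
    keep = active[src] & active[dst]
    src, dst = src[keep], dst[keep]
    data = np.ones(src.shape[0], dtype=np.int8)
    A = sparse.csr_matrix((data, (src, dst)), shape=(graph.n, graph.n))
    if not graph.directed:
        ncomp, labels = csgraph.connected_components(A, directed=False)
        labels = labels[active]
        gcc = int(np.bincount(labels, minlength=ncomp).max()) if labels.size else 0
        return ComponentReport(directed=False, gcc_nodes=gcc, n=graph.n)
    ncomp, labels = csgraph.connected_components(A, directed=True, connection="strong")
    counts = np.bincount(labels[active], minlength=ncomp)
    # isolated active nodes form singleton SCCs; the GSCC is the largest
    giant_label = int(counts.argmax())
    gscc = int(counts[giant_label])
    if gscc <= 1:
        # no non-trivial SCC: by convention GSCC and GOUT are empty
        return ComponentReport(directed=True, gscc_nodes=0, gout_nodes=0, n=graph.n)
    rep = int(np.flatnonzero(active & (labels == giant_label))[0])
    reach = csgraph.breadth_first_order(A, rep, directed=True, return_predecessors=False)
    gout = int(active[reach].sum())
    return ComponentReport(directed=True, gscc_nodes=gscc, gout_nodes=gout, n=graph.n)


@dataclass(frozen=True)
class EnsembleSummary:
    replicates: int
    active_fraction_mean: float
    active_fraction_se: float
    giant_fraction_mean: float
    giant_fraction_se: float


def simulate_ensemble(
    graph_factory: Callable[[int], NetworkGraph],
    params: GrowthParams,
    replicates: int,
    seed: int,
) -> EnsembleSummary:
    """Independent graph + seeding per replicate; mean and SE of the
    active fraction and giant-component fraction of the growth cascade."""
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * replicates) % (2**31)
    pa, pinf = [], []
    for r in range(replicates):
        graph = graph_factory(int(child_seeds[2 * r]))
        init = seed_states(graph, params.q, int(child_seeds[2 * r + 1]))
        result = run_growth(graph, init, params.m)
        pa.append(result.active_fraction)
        pinf.append(components_active(graph, result.final_states).giant_fraction)
    pa_arr, pinf_arr = np.asarray(pa), np.asarray(pinf)

    def _se(a: np.ndarray) -> float:
        return float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0

    return EnsembleSummary(
        replicates=replicates,
        active_fraction_mean=float(pa_arr.mean()),
        active_fraction_se=_se(pa_arr),
        giant_fraction_mean=float(pinf_arr.mean()),
        giant_fraction_se=_se(pinf_arr),
    )


def write_states(states: np.ndarray, sink: IO[str]) -> None:
    """Two-column "node state" text dump for debugging."""
    for i, s in enumerate(np.asarray(states).astype(int).tolist()):
        sink.write(f"{i} {s}\n")


def read_states(source: IO[str]) -> np.ndarray:
    pairs = sorted(
        (int(a), int(b))
        for a, b in (line.split() for line in source if line.strip() and not line.startswith("#"))
    )
    return np.asarray([s for _, s in pairs], dtype=np.int8)
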