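"""Degree distributions, random-graph generators, and edge-list I/O.

Networks are simple graphs (no self-loops, no parallel edges) over nodes
``0 .. n-1``.  Two random families are provided: Erdős–Rényi (Poisson
degrees) and configuration-model scale-free graphs with ``P(k) ∝ k^-γ``
on a bounded support, in both directed and undirected flavours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence, Union

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeDistribution",
    "JointDegreeDistribution",
    "NetworkGraph",
    "poisson_degree_distribution",
    "powerlaw_degree_distribution",
    "joint_powerlaw_distribution",
    "sample_er",
    "sample_configuration",
    "read_edge_list",
    "write_edge_list",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class DegreeDistribution:
    """Probability mass function over non-negative integer degrees.

    Attributes
    ----------
    support : ndarray of int
        Sorted distinct degrees with nonzero (or explicitly retained) mass.
    mass : ndarray of float
        Probability of each support value; sums to 1 within 1e-12.
    """

    support: np.ndarray
    mass: np.ndarray
    mean_degree: float = field(init=False)

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.int64)
        mass = np.asarray(self.mass, dtype=float)
        if support.ndim != 1 or mass.shape != support.shape:
            raise ValueError("support and mass must be 1-D arrays of equal length")
        if np.any(support < 0):
            raise ValueError("degrees must be non-negative")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be sorted and distinct")
        if np.any(mass < 0):
            raise ValueError("masses must be non-negative")
        if abs(mass.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"masses sum to {mass.sum()!r}, not 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)
        object.__setattr__(self, "mean_degree", float(support @ mass))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. degrees."""
        return rng.choice(self.support, size=n, p=self.mass)


@dataclass(frozen=True)
class JointDegreeDistribution:
    """Joint pmf P(kin, kout) over in/out degree pairs.

    ``support`` has shape (N, 2); row i is the pair (kin, kout) with
    probability ``mass[i]``.  A distribution is *synthesizable* as a
    directed graph only when mean in- and out-degree coincide.
    """

    support: np.ndarray
    mass: np.ndarray
    mean_in: float = field(init=False)
    mean_out: float = field(init=False)

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.int64)
        mass = np.asarray(self.mass, dtype=float)
        if support.ndim != 2 or support.shape[1] != 2 or mass.shape != (support.shape[0],):
            raise ValueError("support must be (N, 2) pairs with matching mass")
        if np.any(support < 0) or np.any(mass < 0):
            raise ValueError("degrees and masses must be non-negative")
        if abs(mass.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"masses sum to {mass.sum()!r}, not 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)
        object.__setattr__(self, "mean_in", float(support[:, 0] @ mass))
        object.__setattr__(self, "mean_out", float(support[:, 1] @ mass))

    @property
    def synthesizable(self) -> bool:
        return abs(self.mean_in - self.mean_out) < 1e-9

    def in_marginal(self) -> DegreeDistribution:
        return _aggregate_marginal(self.support[:, 0], self.mass)

    def out_marginal(self) -> DegreeDistribution:
        return _aggregate_marginal(self.support[:, 1], self.mass)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. (kin, kout) pairs; returns shape (n, 2)."""
        idx = rng.choice(self.support.shape[0], size=n, p=self.mass)
        return self.support[idx]


def _aggregate_marginal(values: np.ndarray, mass: np.ndarray) -> DegreeDistribution:
    uniq, inv = np.unique(values, return_inverse=True)
    agg = np.zeros(uniq.shape[0])
    np.add.at(agg, inv, mass)
    return DegreeDistribution(uniq, agg / agg.sum())


class NetworkGraph:
    """Simple graph with 0-based integer nodes and adjacency views.

    For directed graphs edges are ordered pairs (u, v) meaning u → v;
    ``in_adjacency[v]`` lists u's, ``out_adjacency[u]`` lists v's.  For
    undirected graphs the two views are identical.
    """

    __slots__ = ("n", "directed", "_edges", "_in_adj", "_out_adj")

    def __init__(self, n: int, directed: bool, edges: Iterable[tuple[int, int]]):
        if n < 0:
            raise ValueError("n must be non-negative")
        self.n = int(n)
        self.directed = bool(directed)
        canon = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) out of range for n={n}")
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            canon.add((u, v) if directed else (min(u, v), max(u, v)))
        self._edges = canon
        in_adj: list[list[int]] = [[] for _ in range(n)]
        out_adj = in_adj if not directed else [[] for _ in range(n)]
        for u, v in sorted(canon):
            out_adj[u].append(v)
            in_adj[v].append(u)  # when undirected this covers both directions
        self._in_adj = [np.asarray(a, dtype=np.int64) for a in in_adj]
        self._out_adj = (
            self._in_adj if not directed else [np.asarray(a, dtype=np.int64) for a in out_adj]
        )

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        return frozenset(self._edges)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def in_adjacency(self) -> Sequence[np.ndarray]:
        return self._in_adj

    @property
    def out_adjacency(self) -> Sequence[np.ndarray]:
        return self._out_adj

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edges as (sources, targets) arrays; undirected edges once each."""
        if not self._edges:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        arr = np.array(sorted(self._edges), dtype=np.int64)
        return arr[:, 0], arr[:, 1]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "directed" if self.directed else "undirected"
        return f"NetworkGraph(n={self.n}, {kind}, edges={self.n_edges})"


# ---------------------------------------------------------------------------
# Degree distributions


def poisson_degree_distribution(mean: float, tail_tolerance: float = 1e-12) -> DegreeDistribution:
    """Truncated, renormalized Poisson(mean) degree distribution.

    The support is 0..kmax where kmax is the smallest integer whose Poisson
    tail mass falls below ``tail_tolerance``.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if not (0 < tail_tolerance < 1e-6):
        raise ValueError("tail_tolerance must lie in (0, 1e-6)")
    # sf(k) = P(X > k); find smallest kmax with tail beyond kmax below tol
    kmax = int(stats.poisson.isf(tail_tolerance, mean))
    while stats.poisson.sf(kmax, mean) >= tail_tolerance:
        kmax += 1
    support = np.arange(kmax + 1)
    mass = stats.poisson.pmf(support, mean)
    return DegreeDistribution(support, mass / mass.sum())


def powerlaw_degree_distribution(gamma: float, kmin: int = 1, kmax: int = 100) -> DegreeDistribution:
    """Bounded power law P(k) ∝ k^-γ on kmin..kmax, exactly normalized."""
    if kmin > kmax:
        raise ValueError("kmin must not exceed kmax")
    if kmin < 1:
        raise ValueError("kmin must be positive")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    support = np.arange(kmin, kmax + 1)
    mass = support.astype(float) ** (-gamma)
    return DegreeDistribution(support, mass / mass.sum())


def joint_powerlaw_distribution(
    gamma: float, kmin: int = 1, kmax: int = 100
) -> JointDegreeDistribution:
    """Uncorrelated joint power law P(kin, kout) ∝ kin^-γ · kout^-γ."""
    marg = powerlaw_degree_distribution(gamma, kmin, kmax)
    kin, kout = np.meshgrid(marg.support, marg.support, indexing="ij")
    mass = np.outer(marg.mass, marg.mass)
    support = np.column_stack([kin.ravel(), kout.ravel()])
    return JointDegreeDistribution(support, mass.ravel())


# ---------------------------------------------------------------------------
# Samplers


def sample_er(n: int, mean_degree: float, directed: bool, seed: int) -> NetworkGraph:
    """G(n, p) with p = mean_degree / (n-1), per ordered pair when directed."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not (0 <= mean_degree <= n - 1 or n == 1 and mean_degree == 0):
        raise ValueError("mean_degree must lie in [0, n-1]")
    p = 0.0 if n == 1 else mean_degree / (n - 1)
    g = nx.fast_gnp_random_graph(n, p, seed=int(seed), directed=directed)
    return NetworkGraph(n, directed, g.edges())


def _balance_directed_sequence(
    pairs: np.ndarray, dist: JointDegreeDistribution, rng: np.random.Generator
) -> np.ndarray:
    """Resample random nodes' (kin, kout) pairs until stub totals match."""
    max_tries = 200 * pairs.shape[0] + 10_000
    for _ in range(max_tries):
        if pairs[:, 0].sum() == pairs[:, 1].sum():
            return pairs
        i = rng.integers(pairs.shape[0])
        pairs[i] = dist.sample(1, rng)[0]
    raise RuntimeError("could not balance directed degree sequence")


def sample_configuration(
    dist: Union[DegreeDistribution, JointDegreeDistribution], n: int, seed: int
) -> NetworkGraph:
    """Configuration-model graph with i.i.d. degrees from ``dist``.

    Stubs are matched uniformly at random; the result is projected to a
    simple graph (self-loops dropped, parallel edges collapsed).  Directed
    sequences are repaired to equal in/out stub totals by resampling
    uniformly chosen nodes, undirected ones to even total the same way.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if isinstance(dist, JointDegreeDistribution):
        if not dist.synthesizable:
            raise ValueError("joint distribution has unequal mean in/out degree")
        pairs = dist.sample(n, rng)
        pairs = _balance_directed_sequence(pairs, dist, rng)
        out_stubs = np.repeat(np.arange(n), pairs[:, 1])
        in_stubs = np.repeat(np.arange(n), pairs[:, 0])
        rng.shuffle(in_stubs)
        edges = zip(out_stubs.tolist(), in_stubs.tolist())
        return NetworkGraph(n, True, ((u, v) for u, v in edges if u != v))
    degrees = dist.sample(n, rng)
    tries = 0
    while degrees.sum() % 2 == 1:
        degrees[rng.integers(n)] = dist.sample(1, rng)[0]
        tries += 1
        if tries > 100 * n + 10_000:
            raise RuntimeError("could not obtain an even degree sum")
    stubs = np.repeat(np.arange(n), degrees)
    rng.shuffle(stubs)
    half = stubs.shape[0] // 2
    edges = zip(stubs[:half].tolist(), stubs[half:].tolist())
    return NetworkGraph(n, False, ((u, v) for u, v in edges if u != v))


# ---------------------------------------------------------------------------
# Edge-list I/O


def read_edge_list(source: IO[str], directed: bool) -> NetworkGraph:
    """Parse a whitespace "u v" edge list; '#' lines and blanks are skipped.

    Node labels are arbitrary non-negative integers.  Labels that already
    form the canonical range 0..n-1 are kept verbatim (so writing and
    re-reading a graph is the identity); any other label set is compacted
    to 0..n-1 in first-appearance order.  Duplicate edges collapse;
    self-loops are dropped with a warning.
    """
    raw_edges: list[tuple[int, int]] = []
    seen: dict[int, None] = {}
    dropped = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'u v', got {raw!r}")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer node label in {raw!r}") from exc
        if u < 0 or v < 0:
            raise ValueError(f"line {lineno}: negative node label in {raw!r}")
        seen.setdefault(u)
        seen.setdefault(v)
        if u == v:
            dropped += 1
            continue
        raw_edges.append((u, v))
    if dropped:
        logger.warning("dropped %d self-loop line(s) while reading edge list", dropped)
    n = len(seen)
    if set(seen) == set(range(n)):
        edges = raw_edges
    else:
        relabel = {lab: i for i, lab in enumerate(seen)}
        edges = [(relabel[u], relabel[v]) for u, v in raw_edges]
    return NetworkGraph(n, directed, edges)


def write_edge_list(graph: NetworkGraph, sink: IO[str]) -> None:
    """Write one "u v" line per edge (canonical order)."""
    src, dst = graph.edge_arrays()
    for u, v in zip(src.tolist(), dst.tolist()):
        sink.write(f"{u} {v}\n")
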