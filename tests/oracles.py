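"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — pure-Python set arithmetic, literal
nested sums, exhaustive enumeration — and shares no code path with the
package internals it checks.
"""

from __future__ import annotations

import itertools
import math
import random

import numpy as np


# ---------------------------------------------------------------------------
# Graph / cascade oracles


def random_digraph_edges(n: int, p: float, rng: random.Random) -> list[tuple[int, int]]:
    return [
        (u, v)
        for u in range(n)
        for v in range(n)
        if u != v and rng.random() < p
    ]


def in_neighbors(n: int, edges: list[tuple[int, int]], directed: bool) -> list[set[int]]:
    ins: list[set[int]] = [set() for _ in range(n)]
    for u, v in edges:
        ins[v].add(u)
        if not directed:
            ins[u].add(v)
    return ins


def induced_index_bruteforce(
    n: int, edges: list[tuple[int, int]], directed: bool, states, node: int
):
    """Max over active in-neighbors j of node of j's active in-neighbor count."""
    ins = in_neighbors(n, edges, directed)
    best = None
    for j in ins[node]:
        if states[j]:
            count = sum(1 for l in ins[j] if states[l])
            best = count if best is None else max(best, count)
    return best


def growth_full_sweep(
    n: int, edges: list[tuple[int, int]], directed: bool, init, m: int
) -> list[int]:
    """Repeated full sweeps over all nodes until no state changes."""
    states = list(init)
    changed = True
    while changed:
        changed = False
        new_states = list(states)
        for i in range(n):
            if states[i]:
                continue
            idx = induced_index_bruteforce(n, edges, directed, states, i)
            if idx is not None and idx >= m:
                new_states[i] = 1
                changed = True
        states = new_states
    return states


def growth_random_schedule(
    n: int, edges: list[tuple[int, int]], directed: bool, init, m: int,
    rng: random.Random,
) -> list[int]:
    """Asynchronous activation in random order until no node is activatable."""
    states = list(init)
    while True:
        activatable = []
        for i in range(n):
            if states[i]:
                continue
            idx = induced_index_bruteforce(n, edges, directed, states, i)
            if idx is not None and idx >= m:
                activatable.append(i)
        if not activatable:
            return states
        states[rng.choice(activatable)] = 1


def gscc_gout_bruteforce(n: int, edges: list[tuple[int, int]], states):
    """Largest SCC and its out-component of the active subgraph, by
    boolean transitive closure."""
    active = [i for i in range(n) if states[i]]
    reach = np.eye(n, dtype=bool)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        if states[u] and states[v]:
            adj[u, v] = True
    for _ in range(n):
        new = reach | (reach @ adj)
        if (new == reach).all():
            break
        reach = new
    mutual = reach & reach.T
    sccs: dict[frozenset, None] = {}
    for i in active:
        sccs[frozenset(j for j in active if mutual[i, j])] = None
    if not sccs:
        return [(set(), set())]
    best_size = max(len(s) for s in sccs)
    if best_size <= 1:
        return [(set(), set())]
    # ties between equal-size largest SCCs are broken arbitrarily by the
    # implementation, so report every candidate bow-tie
    out = []
    for scc in sccs:
        if len(scc) == best_size:
            rep = next(iter(scc))
            gout = {j for j in active if reach[rep, j]}
            out.append((set(scc), gout))
    return out


# ---------------------------------------------------------------------------
# Binomial / closed-form oracles


def binom_pmf_enumerated(p: float, n: int, s: int) -> float:
    """P(#successes = s) by exhaustive enumeration of outcome strings."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=n):
        if sum(outcome) == s:
            prob = 1.0
            for o in outcome:
                prob *= p if o else (1.0 - p)
            total += prob
    return total


def h_explicit_sum(y: float, xi: float, yi: float, k: int) -> float:
    """Literal sum over the number t of inducing in-neighbors (GOUT term)."""
    total = 0.0
    for t in range(1, k + 1):
        g = math.comb(k, t) * y**t * (1.0 - y) ** (k - t)
        inner_t = (1.0 - yi / y) ** t if y > 0 else 0.0
        rest = (1.0 - (xi - yi) / (1.0 - y)) ** (k - t) if y < 1 else 1.0
        total += g * (1.0 - inner_t * rest)
    return total


def gcc_low_explicit_sum(s: int, xt, yt, beta, gamma_v) -> float:
    """Literal t-sum for the undirected GCC term without induced neighbors."""
    total = 0.0
    for t in range(1, s + 1):
        g = math.comb(s, t) * (yt / xt) ** t * (1.0 - yt / xt) ** (s - t)
        a = (1.0 - gamma_v / yt) ** t if yt > 0 else 0.0
        b = (1.0 - (beta - gamma_v) / (xt - yt)) ** (s - t) if xt > yt else 1.0
        total += g * (1.0 - a * b)
    return total


def gcc_high_explicit_sum(s: int, k: int, xt, yt, alpha, beta, gamma_v) -> float:
    """Literal t-sum for the undirected GCC term with induced neighbors."""
    d = (1.0 - (alpha - beta) / (1.0 - xt)) ** (k - 1 - s) if xt < 1 else 1.0
    total = 0.0
    for t in range(1, s + 1):
        g = math.comb(s, t) * (yt / xt) ** t * (1.0 - yt / xt) ** (s - t)
        a = (1.0 - gamma_v / yt) ** t if yt > 0 else 0.0
        b = (1.0 - (beta - gamma_v) / (xt - yt)) ** (s - t) if xt > yt else 1.0
        total += g * (1.0 - a * b * d)
    return total


# ---------------------------------------------------------------------------
# Literal stage-1 fixed-point maps (direct nested sums, no folding)


def undirected_stage1_literal(support, mass, q: float, m: int, xt: float, yt: float):
    """One literal application of the undirected activation equations."""
    mean_k = float(np.dot(support, mass))
    xt_new = q
    yt_new = 0.0
    for k, pk in zip(support, mass):
        k = int(k)
        if k == 0:
            continue
        w = k * pk / mean_k
        xt_new += (1.0 - q) * w * (1.0 - (1.0 - yt) ** (k - 1))
        for s in range(m, k):
            f = math.comb(k - 1, s) * xt**s * (1.0 - xt) ** (k - 1 - s)
            frac = (1.0 - (1.0 - yt / xt) ** s) if xt > 0 else 0.0
            yt_new += w * f * (q + (1.0 - q) * frac)
    return xt_new, yt_new


def directed_stage1_literal(pairs, mass, q: float, m: int, x: float, y: float):
    """One literal application of the directed activation equations."""
    mean_k = float(np.dot(pairs[:, 1], mass))
    x_new = q
    y_new = 0.0
    for (kin, kout), pm in zip(pairs.tolist(), mass):
        w = kout * pm / mean_k
        x_new += (1.0 - q) * w * (1.0 - (1.0 - y) ** kin)
        for s in range(m, kin + 1):
            f = math.comb(kin, s) * x**s * (1.0 - x) ** (kin - s)
            frac = (1.0 - (1.0 - y / x) ** s) if x > 0 else 0.0
            y_new += w * f * (q + (1.0 - q) * frac)
    return x_new, y_new
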