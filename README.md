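# growperc

Growth-induced percolation on complex networks: cascade simulation,
mean-field theory, and phase-transition analysis.

## The model

Many behaviors spread through *indirect* social influence: what matters is
not just whether your neighbor has adopted, but how strongly that
neighbor is themselves surrounded by adopters.  Growth-induced percolation
captures this with a two-condition activation rule on a network.  Each
node starts active with probability `q`.  An inactive node `i` becomes
active when at least one of its (incoming) neighbors `j` is active **and**
`j` itself has at least `m` active (incoming) neighbors.  Equivalently,
defining the *induced index*

    m_i = max over active in-neighbors j of i of (# active in-neighbors of j),

node `i` activates when `m_i ≥ m`.  The process repeats until no node
changes state; because activations are monotone, the final state is the
unique least fixed point above the seeds, independent of update order.
The reverse (*retention*) process starts fully active, pins the seed
fraction, and deactivates unsupported nodes down to a greatest fixed
point.

The observables are the final active fraction `Pa` and the size `P∞` of
the giant component of the active subgraph — the largest connected
component (GCC) for undirected networks, and the giant out-component
(GOUT, the largest strongly connected component plus everything reachable
from it) for directed ones.

For locally tree-like networks both observables solve closed
self-consistent equations.  For a random directed link `i→j`, `x` is the
probability that `i` is active and `y` the probability that `i` can induce
`j`; a second pair `(x∞, y∞)` of link-level messages gives the GOUT size.
The undirected theory tracks `(x̃, ỹ)` — activity and inducibility along a
link excluding the partner's influence — and a triple `(α, β, γ)` of
conditional connection probabilities for the GCC.  The package solves
these systems for arbitrary (joint) degree distributions, locates critical
points, and classifies transitions as **continuous** (P∞ grows smoothly
from zero at `k_c^I`), **hybrid** (continuous onset followed by a
discontinuous jump at `k_c^II`), or **first-order** (P∞ jumps directly
from zero).

## Worked example

```python
import numpy as np
from growperc import (
    make_fig1a_fixture, induced_index,
    poisson_degree_distribution, solve_undirected,
    sample_er, seed_states, run_growth, components_active,
)

# induced index of the worked-example focal node: max{2, 3} = 3
graph, states, focal = make_fig1a_fixture()
print(induced_index(graph, states, focal))        # -> 3

# theory vs simulation, undirected ER, <k> = 3, q = 0.3, m = 2
theory = solve_undirected(poisson_degree_distribution(3.0), q=0.3, m=2)
print(round(theory.Pa_hat, 4), round(theory.P_inf, 4))   # -> 0.9284 0.9087

g = sample_er(50_000, 3.0, directed=False, seed=1)
final = run_growth(g, seed_states(g, 0.3, seed=2), m=2).final_states
print(round(final.mean(), 4))                             # -> 0.9266
print(round(components_active(g, final).giant_fraction, 4))  # -> 0.9056
```

The theory says that with 30% random seeds on an Erdős–Rényi network of
mean degree 3, indirect induction at threshold `m=2` activates ~92.8% of
all nodes, and 90.9% of nodes end up in the giant active cluster; a
single 50 000-node simulation lands within a few parts per thousand of
both numbers (finite-size fluctuation).

A command-line interface mirrors the library:

```sh
growperc scan --family er --undirected --m 2 --q 0.1 \
    --parameter mean_degree --lo 0.5 --hi 6 --points 40 --out scan.csv
growperc classify --family er --directed --m 2 --q 0.05 \
    --parameter mean_degree --lo 0.5 --hi 10
growperc hysteresis --family er --undirected --m 3 --q 0.19 \
    --parameter mean_degree --lo 0.5 --hi 6 --points 12 --out loop.json
```

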