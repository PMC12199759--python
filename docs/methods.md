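# Methods

## Model

Growth-induced percolation is a monotone cascade on a simple graph.
Nodes are seeded active independently with probability `q`.  An inactive
node activates when some active in-neighbor `j` has at least `m` active
in-neighbors (for undirected graphs, "in-neighbors" means neighbors); the
maximum such count over active in-neighbors is the node's *induced
index*.  A node with no active in-neighbor can never activate, so `m = 0`
reduces the dynamics to reachability from the seed set rather than
spontaneous activation.  When an active `j` is tested for inducing an
inactive `i`, `i` itself is inactive and therefore never counted — this
matches the `k−1` (partner-excluded) convention of the undirected theory.

The cascade engine sweeps synchronously with sparse matrix–vector
products; because the dynamics are monotone the final state is the least
fixed point above the seeds and is independent of schedule (verified
against asynchronous random-schedule and full-sweep oracles).  The
retention process starts fully active, holds a pinned set (threshold 0)
fixed, and removes unsupported nodes until stable — the greatest fixed
point of the support predicate.  During retention the supported node is
itself active and therefore *does* count toward its supporter's active
neighborhood; this small asymmetry matters (see Hysteresis below).

Giant components of the final active subgraph are measured with
`scipy.sparse.csgraph`: the largest connected component (GCC,
undirected), or the largest strongly connected component plus its forward
reachable set (GSCC and GOUT, directed, standard bow-tie definition — the
out-component is obtained by breadth-first search from any GSCC node).
A largest "SCC" of one node (no cycle among actives) reports GSCC = GOUT
= 0.

## Mean-field theory

For tree-like networks the active fraction and the giant-component size
solve two-stage self-consistent systems, solved here for arbitrary degree
distributions on a finite support:

* **Stage 1 (activation).** Directed: link-level probabilities `x`
  (source of a random link is active) and `y` (source can induce its
  target), with the source's in-degree drawn from the out-degree-weighted
  joint distribution; the active fraction `Pa` follows by mixing over the
  node-level in-degree distribution.  Undirected: `x̃`, `ỹ` with the
  edge-weighted excess-degree distribution `k P(k)/⟨k⟩` and neighborhood
  size `k−1`.

* **Stage 2 (giant component).** With stage 1 frozen, directed messages
  `x∞, y∞` give the GOUT size and undirected messages `α, β, γ` the GCC
  size.  The per-degree terms are closed binomial forms (`h_closed`,
  `gcc_term_low`, `gcc_term_high`), each verified against its explicit
  inner sum over the number of inducing neighbors.

The inner sums over the number `s` of active neighbors are folded into
partial binomial sums with at most `m` explicit terms: each term
`F(s)·r^s·D^(n−s)` becomes `C(n,s)·a^s·b^(n−s)` with `a, b` plain
products of the state variables, so one iteration costs `O(m·|support|)`
vectorized numpy work and the conditional-probability ratios never
require explicit 0/0 handling.  In the undirected stage-2 equations the
per-term expressions are taken exactly as derived from the explicit inner
sums; the variant with an extra `(ỹ/x̃)^(k−s)` factor does not follow from
that derivation and is not used.  The implementation is validated against
Monte-Carlo cascades on 50 000-node networks (ER directed and undirected,
and directed/undirected scale-free), which is the decisive arbiter for
these algebraic choices.

**Branches.** Both stages are monotone fixed-point maps.  The lower
branch starts at the activation floor `(q, 0)` and converges to the least
fixed point — the growth process.  The upper branch starts at `(1, 1)`
and converges to the greatest fixed point; its fold is the spinodal
`k*`.  Stage 2 starts at the feasible upper corner (`(x, y)` directed,
`(1, x̃, ỹ)` undirected) and iterates downward; the all-zero root always
exists and is reported as `P∞ = 0` when the iteration collapses below
1e-12.

**Numerics.** Stage-1 tolerance 1e-12, stage-2 tolerance 1e-10, at most
1e6 iterations (non-convergence is flagged, never raised).  Plain
iteration suffers critical slowing near folds, so the driver adds a
safeguarded Aitken Δ² step: an extrapolation is attempted only when two
successive contraction-ratio estimates agree within 5% (a demonstrably
geometric tail), with the step capped so that early transients can never
overshoot past a nearby unstable fixed point and flip the tracked branch
— an effect we observed with unconditional extrapolation at small `q`,
where the distance between stable and unstable roots shrinks with the
state scale.  On termination the remaining geometric tail is projected
out once more, which in particular collapses the spurious
`step/(1−λ)`-sized residue that near-critical stage-2 iterations
otherwise report instead of an exact zero.  Poisson supports are
truncated at tail mass 1e-12 and renormalized; with this truncation the
directed and undirected ER theories agree on the active fraction to
better than 1e-8 (they are formally identical because the size-biased
excess distribution of a Poisson law is again Poisson).

## Phase analysis

`classify_transition` works on the lower-branch curve `P∞(parameter)`
evaluated on a coarse grid (33 points), locates the dominant
discontinuity by bisecting the largest adjacent gap down to
`bisection_tol` (default 1e-6), and bisects the crossing of `onset_eps`
(default 1e-6) for the continuous onset `k_c^I`.  The two sides of a
located jump are re-measured at `k_c^II ± 100·bisection_tol`: directly at
the fold the solver's critical slowing makes side attribution unreliable,
a hundred tolerances away it is unambiguous.  A transition is *hybrid*
when the small side of the jump is already above `onset_eps` and
*first-order* when it is below; *continuous* when no refined gap reaches
`jump_delta` (default 1e-3).  For parameters along which `P∞` decreases
(the scale-free exponent γ), onset and jump keep their meanings with the
axis direction reversed.  Scans warm-start each grid point from its
predecessor on the same branch (continuation), with a cold-start retry on
non-convergence; classification always cold-starts, since the branch
definition is the contract.

`jump_height_curve` records, per seed fraction `q`, the jump location
`k_c^II` and the lower-branch giant-component size right at the jump
(measured at `k_c^II − 100·bisection_tol`), and fits `log P∞(k_c^II)`
against `log q` by ordinary least squares.  `find_critical_q` bisects on
the existence of a jump ≥ `jump_delta` to locate the hybrid/continuous
boundary `q*`.

**Taxonomy grids.**  The desk-scale grids behind the four-family
transition taxonomy scan mean degree for ER (m ∈ {2, 3}, q ∈ {0.05,
0.19, 0.45}) and the seed fraction for scale-free families at three
exponents each.  The scale-free first-order regime sits at small γ where
hubs dominate: undirected networks show a true jump from `P∞ = 0` (below
1e-10) for γ ≲ 2.1 at q ≲ 0.001, directed ones for γ ≲ 1.7 — directed
links do not size-bias the source's in-degree, so the hub–hub
amplification channel that drives the avalanche needs a heavier tail than
in the undirected case.  At intermediate γ the jump coexists with a
microscopic hub-core giant (`P∞ ~ 1e-5` just below the jump), which the
strict 1e-6 onset threshold classifies as hybrid; the hybrid/first-order
boundary is therefore genuinely resolution-dependent, and the grids pick
one exponent per regime so that every classification uses the default
thresholds unchanged.  These microscopic and small-q regimes are exact
statements about the infinite-size equations; finite simulations of a few
times 1e4 nodes do not trigger the hub avalanche (too few hubs) and sit
far below the theory curve there.

## Hysteresis

The forward branch of a hysteresis loop is the lower-branch theory scan.
For the reverse branch the upper branch of the *growth* equations turns
out not to describe the retention process: retention's support count
includes the supported node itself, which weakens the removal condition,
and the simulated retention steady state (undirected ER, m=3, q=0.19)
stays near `Pa ≈ 0.73` at `⟨k⟩ = 2` where the equations' upper branch has
already collapsed to `Pa ≈ 0.19` through a fold.  `hysteresis_loop`
therefore computes the reverse branch by ensemble simulation of the
retention dynamics (default 2 replicates of 30 000 nodes per grid point,
seeds derived deterministically from the master seed and the parameter
value), classified with simulation-scale tolerances (onset 5e-3 — above
the finite-size floor of the largest-component fraction — jump threshold
0.1, bisection to 0.02).  This reproduces the asymmetry of the loop:
growth is hybrid while retention declines continuously, and the retention
curve dominates the growth curve pointwise (greatest vs least fixed
point).  The equations' upper branch remains available via
`scan_parameter(..., branch="upper")` and
`hysteresis_loop(..., reverse_method="upper_branch")`; at `q = 1` the two
equation branches coincide exactly.

## Synthetic data

Erdős–Rényi graphs are sampled edge-by-edge (`networkx.fast_gnp_random_graph`)
with `p = ⟨k⟩/(n−1)` per unordered or ordered pair; the directed variant
therefore has independent Poisson-like in- and out-degrees, matching the
independent-product joint assumed by the ER theory.  Scale-free graphs
use the configuration model with i.i.d. degrees from a bounded power law
(`P(k) ∝ k^−γ`, support 1..100 by default, matching the theory's
truncation): stubs are matched uniformly, then self-loops are dropped and
parallel edges collapsed (simple-graph projection, a vanishing `O(1/n)`
perturbation at the sizes used); directed degree sequences are balanced
by resampling uniformly chosen nodes' degree pairs, which preserves the
target distribution in expectation.  What these generators do *not*
emulate: degree correlations, clustering, and community structure of real
networks — theory–simulation agreement here validates the tree-like
calculation, not the model's fit to any empirical network, though the
edge-list reader accepts arbitrary real networks.

## Validation scales

The test suite solves theory exactly but keeps simulations at desk scale:
50 000-node ER graphs with 10 replicates for the theory-vs-simulation
check (the sparse setting `⟨k⟩ = 1.5`, `m = 2`, five seed
fractions 0.3–0.9 spanning onset to saturation; deeply subcritical seed
fractions are excluded because the simulated largest-component fraction
has an `O(log n / n)` floor where the theory value is exactly zero),
30 000-node retention ensembles for the hysteresis loop, and 20–60-node
graphs for the exhaustive cascade and component oracles.

## Known limitations

* The theory is exact only for locally tree-like graphs; clustered or
  degree-correlated networks will deviate.
* Degree-correlated joint distributions are out of scope (the directed
  sampler and solver assume the product form); a correlated `kin = kout`
  variant was used only as an internal consistency probe.
* The retention reverse branch is simulated, not solved analytically —
  the retention mean-field system is a distinct derivation that the
  growth equations do not contain.
* Critical exponents and finite-size scaling are not computed.
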