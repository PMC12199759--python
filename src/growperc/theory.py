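"""Mean-field theory of growth-induced percolation.

For locally tree-like networks the final active fraction and the giant
component of the active subgraph solve closed systems of self-consistent
equations.  Both the directed and the undirected theory proceed in two
stages:

* **Stage 1** — link-level activation probabilities.  Directed: ``x`` (the
  source of a random link i→j is active) and ``y`` (i can induce j), with
  the active fraction ``Pa``.  Undirected: ``x̃`` (j active absent i's
  induction) and ``ỹ`` (j can induce i), with active fraction ``P̂a``.

* **Stage 2** — giant-component messages with stage 1 frozen.  Directed:
  ``x∞``/``y∞`` (connection to the giant out-component, GOUT) giving
  ``P∞``.  Undirected: ``α``/``β``/``γ`` (connection to the giant
  connected component, GCC) giving ``P∞``.

Each stage is a monotone fixed-point iteration.  The *lower* branch starts
from the activation floor (only initial seeds active) and converges to the
least fixed point — the growth process.  The *upper* branch starts fully
active and converges to the greatest fixed point — the retention process
with the seed fraction pinned.  Stage 2 always starts from the feasible
upper corner and iterates down; collapse below 1e-12 means the giant
component is the trivial (empty) root.

All degree sums are evaluated exactly on the (truncated) support.  Inner
binomial sums over the number of active neighbors s are folded into
partial binomial sums with at most m explicit terms, so one iteration
costs O(m · |support|).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Union

import numpy as np
from scipy.special import comb, gammaln

from .netgen import (
    DegreeDistribution,
    JointDegreeDistribution,
    poisson_degree_distribution,
)

__all__ = [
    "DirectedSolution",
    "UndirectedSolution",
    "binomial_term",
    "h_closed",
    "gcc_term_low",
    "gcc_term_high",
    "solve_directed",
    "solve_undirected",
    "er_joint",
    "solution_to_json",
]

STAGE1_TOL = 1e-12
STAGE2_TOL = 1e-10
MAX_ITER = 1_000_000
_ZERO = 1e-12  # stage-2 collapse threshold: below this the root is trivial


# ---------------------------------------------------------------------------
# Elementary terms


def binomial_term(p: float, n: int, s: int) -> float:
    """C(n, s) p^s (1-p)^(n-s), computed in log space for stability."""
    if not 0 <= s <= n:
        raise ValueError("s must lie in 0..n")
    if p < 0 or p > 1:
        raise ValueError("p must lie in [0, 1]")
    if p == 0.0:
        return 1.0 if s == 0 else 0.0
    if p == 1.0:
        return 1.0 if s == n else 0.0
    log_c = gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)
    return float(np.exp(log_c + s * np.log(p) + (n - s) * np.log1p(-p)))


def h_closed(y: float, xi: float, yi: float, k: int) -> float:
    """Closed form of the GOUT-connection probability for a degree-k node:
    ``1 - (1-y)^k - (1-xi)^k + (1-y-xi+yi)^k``.

    Equals the explicit sum over the number t of inducing in-neighbors of
    the probability that the node connects onward to the giant
    out-component, given it started inactive.
    """
    return 1.0 - (1.0 - y) ** k - (1.0 - xi) ** k + (1.0 - y - xi + yi) ** k


def gcc_term_low(s: int, xt: float, yt: float, beta: float, gamma_v: float) -> float:
    """Undirected per-degree GCC term for a node with s active neighbors
    that cannot induce its inactive neighbors: probability the node is
    activated and connects to the GCC through those s neighbors.

    Closed form ``1 - (1-ỹ/x̃)^s - (1-β/x̃)^s + ((x̃-ỹ-β+γ)/x̃)^s``.
    """
    if xt <= 0:
        return 0.0
    return (
        1.0
        - (1.0 - yt / xt) ** s
        - (1.0 - beta / xt) ** s
        + ((xt - yt - beta + gamma_v) / xt) ** s
    )


def gcc_term_high(
    s: int, k: int, xt: float, yt: float, alpha: float, beta: float, gamma_v: float
) -> float:
    """As :func:`gcc_term_low` but for s large enough that the node can
    induce its remaining k-1-s neighbors, which then also provide routes
    to the GCC with probability (α-β)/(1-x̃) each.
    """
    if xt <= 0:
        return 0.0
    d = 1.0 - (alpha - beta) / (1.0 - xt) if xt < 1.0 else 1.0
    dp = d ** (k - 1 - s)
    return (
        1.0
        - (1.0 - yt / xt) ** s
        - (1.0 - beta / xt) ** s * dp
        + ((xt - yt - beta + gamma_v) / xt) ** s * dp
    )


def _partial_lower(n: np.ndarray, a: float, b: float, c: int, binom: np.ndarray) -> np.ndarray:
    """sum_{s=0}^{c-1} C(n, s) a^s b^(n-s), vectorized over the degree array n.

    ``binom[:, s]`` caches C(n, s); a, b >= 0 and c is small (<= m+1).
    """
    if c <= 0:
        return np.zeros_like(n, dtype=float)
    total = np.zeros_like(n, dtype=float)
    for s in range(c):
        with np.errstate(invalid="ignore", divide="ignore"):
            term = binom[:, s] * (a**s) * np.power(b, n - s, dtype=float)
        total += np.where(n >= s, term, 0.0)
    return total


def _binom_cache(n: np.ndarray, c: int) -> np.ndarray:
    cols = max(c, 1)
    out = np.zeros((n.shape[0], cols))
    for s in range(cols):
        out[:, s] = comb(n, s)
    out[n[:, None] < np.arange(cols)[None, :]] = 0.0
    return out


# ---------------------------------------------------------------------------
# Solutions


@dataclass(frozen=True)
class DirectedSolution:
    q: float
    m: int
    branch: str
    x: float
    y: float
    x_inf: float
    y_inf: float
    Pa: float
    P_inf: float
    converged: bool
    iterations: int
    residual: float


@dataclass(frozen=True)
class UndirectedSolution:
    q: float
    m: int
    branch: str
    x_t: float
    y_t: float
    alpha: float
    beta: float
    gamma_v: float
    Pa_hat: float
    P_inf: float
    converged: bool
    iterations: int
    residual: float


def solution_to_json(sol: Union[DirectedSolution, UndirectedSolution]) -> str:
    return json.dumps(asdict(sol), sort_keys=True)


def _check_branch(branch: str) -> None:
    if branch not in ("lower", "upper"):
        raise ValueError("branch must be 'lower' or 'upper'")


# ---------------------------------------------------------------------------
# Directed theory


def solve_directed(
    dist: JointDegreeDistribution,
    q: float,
    m: int,
    branch: str = "lower",
    tol: float = STAGE1_TOL,
    max_iter: int = MAX_ITER,
    init: tuple[float, float] | None = None,
    accelerate: bool = True,
) -> DirectedSolution:
    """Solve the directed mean-field system for active fraction and GOUT.

    ``branch`` selects the fixed point of the monotone stage-1 map: the
    lower branch (growth) starts at (x, y) = (q, 0), the upper branch
    (retention with the seed fraction pinned) at (1, 1).  ``init``
    optionally warm-starts stage 1 (continuation along a scan).
    """
    _check_branch(branch)
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if m < 0:
        raise ValueError("m must be non-negative")

    # collapse the joint pmf onto in-degree: edge weight w(kin) and node pmf
    in_marg = dist.in_marginal()
    kin = in_marg.support.astype(np.int64)
    p_in = in_marg.mass
    mean_k = dist.mean_out
    w = np.zeros_like(p_in)
    np.add.at(
        w,
        np.searchsorted(kin, dist.support[:, 0]),
        dist.support[:, 1] * dist.mass / mean_k,
    )
    binom = _binom_cache(kin, m)

    def stage1_map(x: float, y: float) -> tuple[float, float]:
        x_new = q + (1.0 - q) * float(w @ (1.0 - np.power(1.0 - y, kin, dtype=float)))
        t1 = 1.0 - _partial_lower(kin, x, 1.0 - x, m, binom)
        a_y = max(x - y, 0.0)
        t2 = np.power(1.0 - y, kin, dtype=float) - _partial_lower(kin, a_y, 1.0 - x, m, binom)
        y_new = float(w @ (t1 - (1.0 - q) * t2))
        return min(max(x_new, 0.0), 1.0), min(max(y_new, 0.0), 1.0)

    z0 = init if init is not None else ((q, 0.0) if branch == "lower" else (1.0, 1.0))
    (x, y), it1, res1, conv1 = _iterate(stage1_map, z0, tol, max_iter, accelerate)

    Pa = q + (1.0 - q) * float(p_in @ (1.0 - np.power(1.0 - y, kin, dtype=float)))

    def stage2_map(xi: float, yi: float) -> tuple[float, float]:
        pow_xi = np.power(1.0 - xi, kin, dtype=float)
        z = max(1.0 - y - xi + yi, 0.0)
        h = 1.0 - np.power(1.0 - y, kin, dtype=float) - pow_xi + np.power(z, kin, dtype=float)
        xi_new = q * float(w @ (1.0 - pow_xi)) + (1.0 - q) * float(w @ h)
        t1 = 1.0 - _partial_lower(kin, x, 1.0 - x, m, binom)
        t_y = np.power(1.0 - y, kin, dtype=float) - _partial_lower(
            kin, max(x - y, 0.0), 1.0 - x, m, binom
        )
        t_xi = pow_xi - _partial_lower(kin, max(x - xi, 0.0), 1.0 - x, m, binom)
        t_z = np.power(z, kin, dtype=float) - _partial_lower(
            kin, max(x - y - xi + yi, 0.0), 1.0 - x, m, binom
        )
        yi_new = float(w @ (t1 - t_xi - (1.0 - q) * (t_y - t_z)))
        yi_new = min(max(yi_new, 0.0), 1.0)
        xi_new = min(max(xi_new, 0.0), 1.0)
        return xi_new, yi_new

    (xi, yi), it2, res2, conv2 = _iterate(stage2_map, (x, y), STAGE2_TOL, max_iter, accelerate)
    if max(xi, yi) < _ZERO:
        xi = yi = 0.0
    z = max(1.0 - y - xi + yi, 0.0)
    P_inf = q * float(p_in @ (1.0 - np.power(1.0 - xi, kin, dtype=float))) + (1.0 - q) * float(
        p_in
        @ (
            1.0
            - np.power(1.0 - y, kin, dtype=float)
            - np.power(1.0 - xi, kin, dtype=float)
            + np.power(z, kin, dtype=float)
        )
    )
    P_inf = min(max(P_inf, 0.0), 1.0)
    if P_inf < _ZERO:
        P_inf = 0.0
    return DirectedSolution(
        q=q,
        m=m,
        branch=branch,
        x=x,
        y=y,
        x_inf=xi,
        y_inf=yi,
        Pa=Pa,
        P_inf=P_inf,
        converged=conv1 and conv2,
        iterations=it1 + it2,
        residual=max(res1, res2),
    )


def _iterate(fmap, z0: tuple, tol: float, max_iter: int, accelerate: bool = True):
    """Iterate a monotone map to tolerance; returns (z, iters, residual, ok).

    With ``accelerate`` a safeguarded Aitken Δ² step is attempted every few
    iterations: when the per-component contraction ratio is stable and
    strictly below 1, the geometric tail is summed in closed form.  The
    overshoot of the extrapolation is second order in the remaining error,
    so away from a fold it stays inside the basin of the tracked fixed
    point; convergence is still certified by a plain iteration step.
    """
    z = np.array(z0, dtype=float)
    resid = np.inf
    hist: list[np.ndarray] = [z]
    for it in range(1, int(max_iter) + 1):
        z_new = np.asarray(fmap(*z), dtype=float)
        resid = float(np.max(np.abs(z_new - z)))
        z = z_new
        if resid < tol:
            if accelerate:
                # near-critical contraction can satisfy the step tolerance
                # while still far from the limit (step ≈ distance × (1-λ));
                # project onto the geometric limit before reporting
                z1 = np.asarray(fmap(*z), dtype=float)
                z2 = np.asarray(fmap(*z1), dtype=float)
                d1, d2 = z1 - z, z2 - z1
                ok = np.abs(d1) > 0
                lam = np.where(ok, d2 / np.where(ok, d1, 1.0), 0.0)
                good = ok & (lam > 0.0) & (lam < 1.0)
                safe = np.where(good, 1.0 - lam, 1.0)
                factor = np.where(good, np.minimum(lam / safe, 1e7), 0.0)
                z = np.clip(z2 + d2 * factor, 0.0, 1.0)
            return tuple(z), it, resid, True
        hist.append(z)
        if accelerate and len(hist) == 4:
            z0, z1, z2, z3 = hist
            d1, d2, d3 = z1 - z0, z2 - z1, z3 - z2
            ok = (np.abs(d1) > 0) & (np.abs(d2) > 0)
            lam_a = np.where(ok, d2 / np.where(np.abs(d1) > 0, d1, 1.0), 0.0)
            lam_b = np.where(ok, d3 / np.where(np.abs(d2) > 0, d2, 1.0), 0.0)
            # only extrapolate a tail that is demonstrably geometric: the
            # two successive ratio estimates must agree; transients (where
            # Aitken could overshoot past a nearby unstable fixed point and
            # flip the tracked branch) then never trigger a step
            geometric = (
                np.all(ok)
                and np.all((lam_a > 0.0) & (lam_b > 0.0) & (lam_b < 1.0))
                and np.all(np.abs(lam_b - lam_a) <= 0.05 * lam_b)
            )
            if geometric:
                # capped geometric-tail sum; for the monotone concave
                # approach the measured ratio underestimates the asymptotic
                # one, so the step undershoots the fixed point
                factor = np.minimum(lam_b / (1.0 - lam_b), 1e4)
                z = np.clip(z3 + d3 * factor, 0.0, 1.0)
            hist = [z]
    return tuple(z), int(max_iter), resid, False


# ---------------------------------------------------------------------------
# Undirected theory


def solve_undirected(
    dist: DegreeDistribution,
    q: float,
    m: int,
    branch: str = "lower",
    tol: float = STAGE1_TOL,
    max_iter: int = MAX_ITER,
    init: tuple[float, float] | None = None,
    accelerate: bool = True,
) -> UndirectedSolution:
    """Solve the undirected mean-field system for active fraction and GCC.

    Branch semantics match :func:`solve_directed`.  The stage-2 messages
    use the per-degree terms of :func:`gcc_term_low` / :func:`gcc_term_high`
    aggregated into partial binomial sums.
    """
    _check_branch(branch)
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if m < 0:
        raise ValueError("m must be non-negative")
    k = dist.support.astype(np.int64)
    pk = dist.mass
    mean_k = dist.mean_degree
    if mean_k <= 0:
        raise ValueError("distribution must have positive mean degree")
    # edge-weighted quantities only involve k >= 1 (k=0 has edge weight 0)
    pos = k >= 1
    ke, pke = k[pos], pk[pos]
    w = ke * pke / mean_k
    n = ke - 1  # excess degree: neighbors excluding the link endpoint
    c_hi = max(m - 1, 0)  # split of the s-range at m-1 for edge messages
    cols = max(m + 1, 1)
    binom_n = _binom_cache(n, cols)
    binom_k = _binom_cache(k, cols)

    def stage1_map(xt: float, yt: float) -> tuple[float, float]:
        xt_new = q + (1.0 - q) * float(w @ (1.0 - np.power(1.0 - yt, n, dtype=float)))
        t1 = 1.0 - _partial_lower(n, xt, 1.0 - xt, m, binom_n)
        t2 = np.power(1.0 - yt, n, dtype=float) - _partial_lower(
            n, max(xt - yt, 0.0), 1.0 - xt, m, binom_n
        )
        yt_new = float(w @ (t1 - (1.0 - q) * t2))
        return min(max(xt_new, 0.0), 1.0), min(max(yt_new, 0.0), 1.0)

    z0 = init if init is not None else ((q, 0.0) if branch == "lower" else (1.0, 1.0))
    (xt, yt), it1, res1, conv1 = _iterate(stage1_map, z0, tol, max_iter, accelerate)

    Pa_hat = q + (1.0 - q) * float(pk @ (1.0 - np.power(1.0 - yt, k, dtype=float)))

    b0 = 1.0 - xt

    def clip(v: float) -> float:
        return max(v, 0.0)

    def stage2_map(al: float, be: float, ga: float) -> tuple[float, float, float]:
        a_b = clip(xt - be)
        a_y = clip(xt - yt)
        a_g = clip(xt - yt - be + ga)
        bD = clip(1.0 - xt - al + be)  # (1-x̃) · [1 - (α-β)/(1-x̃)]
        one_minus_yt_n = np.power(1.0 - yt, n, dtype=float)
        ab_bD_n = np.power(a_b + bD, n, dtype=float)
        ag_bD_n = np.power(a_g + bD, n, dtype=float)
        # α: 1 - Σ_{s<m-1}F(1-β/x̃)^s ... folded (see module docstring)
        al_new = float(
            w
            @ (
                1.0
                - _partial_lower(n, a_b, b0, c_hi, binom_n)
                - ab_bD_n
                + _partial_lower(n, a_b, bD, c_hi, binom_n)
            )
        )
        # β: qα + (1-q)·[low terms (s ≤ m-2) + high terms (s ≥ m-1)]
        inner = (
            1.0
            - one_minus_yt_n
            - _partial_lower(n, a_b, b0, c_hi, binom_n)
            + _partial_lower(n, a_g, b0, c_hi, binom_n)
            - ab_bD_n
            + _partial_lower(n, a_b, bD, c_hi, binom_n)
            + ag_bD_n
            - _partial_lower(n, a_g, bD, c_hi, binom_n)
        )
        be_new = q * al + (1.0 - q) * float(w @ inner)
        # γ: both initial states restrict to s ≥ m
        tq = (
            1.0
            - _partial_lower(n, xt, b0, m, binom_n)
            - ab_bD_n
            + _partial_lower(n, a_b, bD, m, binom_n)
        )
        tnq = (
            1.0
            - _partial_lower(n, xt, b0, m, binom_n)
            - (one_minus_yt_n - _partial_lower(n, a_y, b0, m, binom_n))
            - (ab_bD_n - _partial_lower(n, a_b, bD, m, binom_n))
            + (ag_bD_n - _partial_lower(n, a_g, bD, m, binom_n))
        )
        ga_new = q * float(w @ tq) + (1.0 - q) * float(w @ tnq)
        al_new = min(max(al_new, 0.0), 1.0)
        be_new = min(max(be_new, 0.0), min(al_new, xt))
        ga_new = min(max(ga_new, 0.0), min(be_new, yt))
        return al_new, be_new, ga_new

    # feasible upper corner
    (al, be, ga), it2, resid2, conv2 = _iterate(
        stage2_map, (1.0, xt, yt), STAGE2_TOL, max_iter, accelerate
    )
    if max(al, be, ga) < _ZERO:
        al = be = ga = 0.0

    a_b = clip(xt - be)
    a_y = clip(xt - yt)
    a_g = clip(xt - yt - be + ga)
    bD = clip(1.0 - xt - al + be)
    lowq = _partial_lower(k, xt, b0, m, binom_k) - _partial_lower(k, a_b, b0, m, binom_k)
    highq = (
        1.0
        - _partial_lower(k, xt, b0, m, binom_k)
        - (np.power(a_b + bD, k, dtype=float) - _partial_lower(k, a_b, bD, m, binom_k))
    )
    low = (
        _partial_lower(k, xt, b0, m, binom_k)
        - _partial_lower(k, a_y, b0, m, binom_k)
        - _partial_lower(k, a_b, b0, m, binom_k)
        + _partial_lower(k, a_g, b0, m, binom_k)
    )
    high = (
        1.0
        - _partial_lower(k, xt, b0, m, binom_k)
        - (np.power(1.0 - yt, k, dtype=float) - _partial_lower(k, a_y, b0, m, binom_k))
        - (np.power(a_b + bD, k, dtype=float) - _partial_lower(k, a_b, bD, m, binom_k))
        + (np.power(a_g + bD, k, dtype=float) - _partial_lower(k, a_g, bD, m, binom_k))
    )
    P_inf = q * float(pk @ (lowq + highq)) + (1.0 - q) * float(pk @ (low + high))
    P_inf = min(max(P_inf, 0.0), 1.0)
    if P_inf < _ZERO:
        P_inf = 0.0
    return UndirectedSolution(
        q=q,
        m=m,
        branch=branch,
        x_t=xt,
        y_t=yt,
        alpha=al,
        beta=be,
        gamma_v=ga,
        Pa_hat=Pa_hat,
        P_inf=P_inf,
        converged=conv1 and conv2,
        iterations=it1 + it2,
        residual=max(res1, resid2),
    )


def er_joint(mean: float, tail_tolerance: float = 1e-12) -> JointDegreeDistribution:
    """Product of two equal-mean truncated Poisson marginals (directed ER)."""
    marg = poisson_degree_distribution(mean, tail_tolerance)
    kin, kout = np.meshgrid(marg.support, marg.support, indexing="ij")
    mass = np.outer(marg.mass, marg.mass)
    return JointDegreeDistribution(
        np.column_stack([kin.ravel(), kout.ravel()]), mass.ravel()
    )
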