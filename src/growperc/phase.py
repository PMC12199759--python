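"""Phase-transition analysis: parameter scans, transition classification,
critical points, jump-height scaling, and hysteresis loops.

A :class:`ModelSpec` names a network family (ER or scale-free), the
directedness, and the cascade parameters (q, m); it solves the mean-field
theory at any value of a chosen control parameter (``mean_degree``,
``gamma`` or ``q``) on either fixed-point branch.  Classification then
works on the lower-branch curve P∞(parameter):

* *continuous* — P∞ crosses zero smoothly (no discontinuity anywhere on
  the refined grid larger than ``jump_delta``); the onset is kcI;
* *hybrid* — a continuous onset at kcI followed by a discontinuous jump
  at kcII > kcI (P∞ just on the small side of the jump already nonzero);
* *first-order* — P∞ jumps directly from (numerically) zero, kcI = kcII.

Jumps are located by interval bisection on the largest adjacent-point gap;
a genuine discontinuity keeps a gap ≥ jump_delta at arbitrarily small
interval width, while continuous variation decays with the width.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from typing import IO, Optional, Sequence, Union

import numpy as np

from .netgen import (
    DegreeDistribution,
    JointDegreeDistribution,
    joint_powerlaw_distribution,
    poisson_degree_distribution,
    powerlaw_degree_distribution,
)
from .theory import (
    DirectedSolution,
    UndirectedSolution,
    er_joint,
    solve_directed,
    solve_undirected,
)

__all__ = [
    "ModelSpec",
    "ScanResult",
    "TransitionReport",
    "HysteresisResult",
    "scan_parameter",
    "classify_transition",
    "find_critical_q",
    "jump_height_curve",
    "hysteresis_loop",
    "table2_taxonomy",
    "write_scan_csv",
]

ONSET_EPS = 1e-6
JUMP_DELTA = 1e-3
BISECTION_TOL = 1e-6

Solution = Union[DirectedSolution, UndirectedSolution]


@dataclass(frozen=True)
class ModelSpec:
    """A solvable model: network family + cascade parameters.

    family "er" uses ``mean_degree``; family "sf" uses a bounded power law
    with exponent ``gamma`` on ``kmin..kmax``.
    """

    family: str  # "er" | "sf"
    directed: bool
    q: float
    m: int
    mean_degree: Optional[float] = None
    gamma: Optional[float] = None
    kmin: int = 1
    kmax: int = 100
    tail_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if self.family not in ("er", "sf"):
            raise ValueError("family must be 'er' or 'sf'")
        if self.family == "er" and self.mean_degree is None:
            raise ValueError("ER family requires mean_degree")
        if self.family == "sf" and self.gamma is None:
            raise ValueError("SF family requires gamma")

    def with_param(self, name: str, value: float) -> "ModelSpec":
        if name not in ("mean_degree", "gamma", "q"):
            raise ValueError(f"unknown control parameter {name!r}")
        return replace(self, **{name: float(value)})

    def distribution(self) -> Union[DegreeDistribution, JointDegreeDistribution]:
        if self.family == "er":
            if self.directed:
                return er_joint(self.mean_degree, self.tail_tolerance)
            return poisson_degree_distribution(self.mean_degree, self.tail_tolerance)
        if self.directed:
            return joint_powerlaw_distribution(self.gamma, self.kmin, self.kmax)
        return powerlaw_degree_distribution(self.gamma, self.kmin, self.kmax)

    def solve(
        self, branch: str = "lower", init: tuple[float, float] | None = None
    ) -> Solution:
        dist = self.distribution()
        if self.directed:
            return solve_directed(dist, self.q, self.m, branch=branch, init=init)
        return solve_undirected(dist, self.q, self.m, branch=branch, init=init)

    def sample(self, n: int, seed: int):
        """Draw one random graph of this family (for simulation branches)."""
        from .netgen import sample_configuration, sample_er

        if self.family == "er":
            return sample_er(n, self.mean_degree, self.directed, seed)
        return sample_configuration(self.distribution(), n, seed)


def _pa(sol: Solution) -> float:
    return sol.Pa if isinstance(sol, DirectedSolution) else sol.Pa_hat


def _stage1(sol: Solution) -> tuple[float, float]:
    if isinstance(sol, DirectedSolution):
        return (sol.x, sol.y)
    return (sol.x_t, sol.y_t)


@dataclass(frozen=True)
class ScanResult:
    parameter: str
    grid: np.ndarray
    Pa_lower: np.ndarray
    P_inf_lower: np.ndarray
    Pa_upper: Optional[np.ndarray] = None
    P_inf_upper: Optional[np.ndarray] = None
    converged: Optional[np.ndarray] = None


@dataclass(frozen=True)
class TransitionReport:
    type: str  # none | continuous | hybrid | first_order
    kcI: Optional[float] = None
    kcII: Optional[float] = None
    jump_height: float = 0.0
    spinodal_kstar: Optional[float] = None
    onset_eps: float = ONSET_EPS
    jump_delta: float = JUMP_DELTA
    bisection_tol: float = BISECTION_TOL

    def to_json(self) -> str:
        return json.dumps(
            {k: getattr(self, k) for k in (
                "type", "kcI", "kcII", "jump_height", "spinodal_kstar",
                "onset_eps", "jump_delta", "bisection_tol",
            )},
            sort_keys=True,
        )


@dataclass(frozen=True)
class HysteresisResult:
    forward: ScanResult
    reverse: ScanResult
    forward_report: TransitionReport
    reverse_report: TransitionReport
    loop_gap: float = field(init=False)

    def __post_init__(self) -> None:
        gap = float(np.max(self.reverse.P_inf_lower - self.forward.P_inf_lower))
        object.__setattr__(self, "loop_gap", max(gap, 0.0))


def scan_parameter(
    spec: ModelSpec,
    parameter: str,
    grid: Sequence[float],
    branch: str = "lower",
) -> ScanResult:
    """Solve the theory along ``grid``, warm-starting each point from the
    previous one on the same branch (continuation), with a cold-start
    retry whenever continuation fails to converge."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty and strictly increasing")
    branches = ("lower", "upper") if branch == "both" else (branch,)
    results: dict[str, list[Solution]] = {}
    for br in branches:
        sols: list[Solution] = []
        # track the upper branch from the high-parameter end downward
        order = grid if br == "lower" else grid[::-1]
        init: tuple[float, float] | None = None
        for value in order:
            point = spec.with_param(parameter, value)
            sol = point.solve(branch=br, init=init)
            if not sol.converged:
                sol = point.solve(branch=br)  # cold-start fallback
            sols.append(sol)
            init = _stage1(sol)
        if br == "upper":
            sols = sols[::-1]
        results[br] = sols
    lower = results.get("lower") or results.get("upper")
    out = ScanResult(
        parameter=parameter,
        grid=grid,
        Pa_lower=np.array([_pa(s) for s in results[branches[0]]]),
        P_inf_lower=np.array([s.P_inf for s in results[branches[0]]]),
        converged=np.array([s.converged for s in results[branches[0]]]),
    )
    if len(branches) == 2:
        out = replace(
            out,
            Pa_upper=np.array([_pa(s) for s in results["upper"]]),
            P_inf_upper=np.array([s.P_inf for s in results["upper"]]),
        )
    return out


def _p_inf_at(spec: ModelSpec, parameter: str, value: float, branch: str) -> float:
    return spec.with_param(parameter, value).solve(branch=branch).P_inf


def _refine_jump(
    f, lo: float, hi: float, v_lo: float, v_hi: float, jump_delta: float, tol: float
) -> tuple[float, float, float, float]:
    """Bisect the largest-gap subinterval of [lo, hi] down to width ``tol``.

    Returns (lo, hi, v_lo, v_hi) of the final interval; the gap v_hi - v_lo
    persists for a genuine discontinuity and decays for a continuous curve.
    """
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        v_mid = f(mid)
        if abs(v_mid - v_lo) >= abs(v_hi - v_mid):
            hi, v_hi = mid, v_mid
        else:
            lo, v_lo = mid, v_mid
        if abs(v_hi - v_lo) < jump_delta * 0.01:
            break  # gap has collapsed: no discontinuity here
    return lo, hi, v_lo, v_hi


def _bisect_onset(f, lo: float, hi: float, onset_eps: float, tol: float) -> float:
    """Bisect the crossing of P∞ = onset_eps; assumes f(lo) < eps <= f(hi)."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) >= onset_eps:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def classify_transition(
    spec: ModelSpec,
    parameter: str,
    bracket: tuple[float, float],
    onset_eps: float = ONSET_EPS,
    jump_delta: float = JUMP_DELTA,
    bisection_tol: float = BISECTION_TOL,
    coarse_points: int = 33,
    solver=None,
    edge_offset: Optional[float] = None,
) -> TransitionReport:
    """Classify the lower-branch transition of P∞ along ``parameter``.

    ``solver`` may override the theory call (signature (value) -> P∞),
    which the tests use to plant synthetic ground-truth curves.
    ``edge_offset`` is the distance from a located jump at which the two
    sides of the discontinuity are measured (default 100x bisection_tol);
    it keeps the side evaluations out of the solver's critical
    slowing-down zone right at the fold.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    if edge_offset is None:
        edge_offset = 100.0 * bisection_tol
    f = solver if solver is not None else (
        lambda v: _p_inf_at(spec, parameter, v, "lower")
    )
    grid = np.linspace(lo, hi, coarse_points)
    vals = np.array([f(v) for v in grid])

    # orient so that P∞ is (weakly) increasing along the search direction
    increasing = vals[-1] >= vals[0]

    # 1. locate the dominant candidate discontinuity
    gaps = np.abs(np.diff(vals))
    j = int(np.argmax(gaps))
    jump_height = 0.0
    kcII: Optional[float] = None
    v_small_side = None
    if gaps[j] >= jump_delta:
        a, b, va, vb = _refine_jump(
            f, grid[j], grid[j + 1], vals[j], vals[j + 1], jump_delta, bisection_tol
        )
        if abs(vb - va) >= jump_delta:
            kcII = 0.5 * (a + b)
            # re-measure both sides at a safe distance from the jump
            v_below = f(kcII - edge_offset)
            v_above = f(kcII + edge_offset)
            jump_height = abs(v_above - v_below)
            v_small_side = min(v_below, v_above)
            if jump_height < jump_delta:
                kcII = None  # steep but continuous after all

    # 2. locate the continuous onset (crossing of onset_eps) on the
    #    zero side of the curve
    kcI: Optional[float] = None
    above = vals >= onset_eps
    if above.any() and not above.all():
        # find a bracketing pair on the coarse grid
        flip = np.flatnonzero(np.diff(above.astype(int)) != 0)
        i = int(flip[0] if increasing else flip[-1])
        a, b = grid[i], grid[i + 1]
        if above[i + 1] and not above[i]:
            kcI = _bisect_onset(f, a, b, onset_eps, bisection_tol)
        else:  # decreasing curve: crossing from above to below
            kcI = -_bisect_onset(lambda v: f(-v), -b, -a, onset_eps, bisection_tol)

    if kcII is not None:
        if v_small_side is not None and v_small_side < onset_eps:
            return TransitionReport(
                type="first_order",
                kcI=kcII,
                kcII=kcII,
                jump_height=jump_height,
                onset_eps=onset_eps,
                jump_delta=jump_delta,
                bisection_tol=bisection_tol,
            )
        return TransitionReport(
            type="hybrid",
            kcI=kcI,
            kcII=kcII,
            jump_height=jump_height,
            onset_eps=onset_eps,
            jump_delta=jump_delta,
            bisection_tol=bisection_tol,
        )
    if kcI is not None:
        return TransitionReport(
            type="continuous",
            kcI=kcI,
            onset_eps=onset_eps,
            jump_delta=jump_delta,
            bisection_tol=bisection_tol,
        )
    return TransitionReport(
        type="none",
        onset_eps=onset_eps,
        jump_delta=jump_delta,
        bisection_tol=bisection_tol,
    )


def find_critical_q(
    spec: ModelSpec,
    parameter: str,
    bracket: tuple[float, float],
    q_bracket: tuple[float, float],
    jump_delta: float = JUMP_DELTA,
    tol: float = 1e-3,
) -> float:
    """Critical seed fraction q* separating hybrid from continuous regimes.

    Bisection on the existence of a lower-branch jump ≥ jump_delta along
    ``parameter`` within ``bracket``; the jump must exist at q_bracket[0]
    and be absent at q_bracket[1].
    """

    def has_jump(q: float) -> bool:
        rep = classify_transition(
            spec.with_param("q", q), parameter, bracket, jump_delta=jump_delta
        )
        return rep.type in ("hybrid", "first_order")

    q_lo, q_hi = float(q_bracket[0]), float(q_bracket[1])
    if not has_jump(q_lo):
        raise ValueError(f"no jump at q={q_lo}: bracket does not straddle q*")
    if has_jump(q_hi):
        raise ValueError(f"jump persists at q={q_hi}: bracket does not straddle q*")
    while q_hi - q_lo > tol:
        q_mid = 0.5 * (q_lo + q_hi)
        if has_jump(q_mid):
            q_lo = q_mid
        else:
            q_hi = q_mid
    return 0.5 * (q_lo + q_hi)


@dataclass(frozen=True)
class JumpPoint:
    q: float
    kcII: float
    height: float  # P∞ of the lower branch at the jump point (small side)
    gap: float  # size of the discontinuity


@dataclass(frozen=True)
class JumpScaling:
    points: tuple[JumpPoint, ...]
    exponent: float
    intercept: float
    r_squared: float


def jump_height_curve(
    spec: ModelSpec,
    parameter: str,
    bracket: tuple[float, float],
    q_grid: Sequence[float],
    jump_delta: float = JUMP_DELTA,
) -> JumpScaling:
    """Jump location per q, with a log-log least-squares fit of P∞(kcII)
    against q: the lower-branch giant-component size right at the jump
    point grows as a power of the seed fraction."""
    points: list[JumpPoint] = []
    for q in q_grid:
        qspec = spec.with_param("q", q)
        rep = classify_transition(qspec, parameter, bracket, jump_delta=jump_delta)
        if rep.kcII is None:
            continue  # q beyond the critical q*: no jump to record
        offset = 100.0 * rep.bisection_tol
        small = _p_inf_at(qspec, parameter, rep.kcII - offset, "lower")
        points.append(
            JumpPoint(q=float(q), kcII=rep.kcII, height=small, gap=rep.jump_height)
        )
    if len(points) < 2:
        raise ValueError("fewer than two jump points found in q_grid")
    lx = np.log([p.q for p in points])
    ly = np.log([p.height for p in points])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return JumpScaling(
        points=tuple(points), exponent=float(slope), intercept=float(intercept),
        r_squared=r2,
    )


def _retention_point(
    spec: ModelSpec, parameter: str, value: float, n: int, replicates: int, seed: int
) -> tuple[float, float]:
    """Mean (Pa, P∞) of the retention process at one parameter value.

    Seeds are derived from the master seed and the parameter value so that
    repeated evaluation at the same value (e.g. during bisection) is
    deterministic."""
    from .dynamics import components_active, run_retention, seed_states

    point = spec.with_param(parameter, value)
    salt = int.from_bytes(np.float64(value).tobytes(), "little") % (2**31)
    base = np.random.SeedSequence([seed, salt]).generate_state(2 * replicates) % (2**31)
    pa, pinf = [], []
    for r in range(replicates):
        g = point.sample(n, int(base[2 * r]))
        pinned = np.flatnonzero(seed_states(g, point.q, int(base[2 * r + 1])))
        res = run_retention(g, pinned, point.m)
        pa.append(res.active_fraction)
        pinf.append(components_active(g, res.final_states).giant_fraction)
    return float(np.mean(pa)), float(np.mean(pinf))


# classification tolerances for simulated (finite-size, noisy) curves
SIM_ONSET_EPS = 5e-3
SIM_JUMP_DELTA = 0.1
SIM_BISECTION_TOL = 0.02


def hysteresis_loop(
    spec: ModelSpec,
    parameter: str,
    grid: Sequence[float],
    onset_eps: float = ONSET_EPS,
    jump_delta: float = JUMP_DELTA,
    bisection_tol: float = BISECTION_TOL,
    reverse_method: str = "retention",
    n: int = 30_000,
    replicates: int = 2,
    seed: int = 0,
) -> HysteresisResult:
    """Growth-vs-retention hysteresis loop over ``grid``.

    The forward branch is the lower-branch (growth) theory scan.  The
    reverse branch is, by default, an ensemble simulation of the retention
    process (all nodes initially active, the seed fraction q pinned at
    threshold 0, everyone else at threshold m), classified with
    simulation-scale tolerances; ``reverse_method="upper_branch"`` instead
    tracks the greatest fixed point of the same theory equations (the
    branch whose fold is the spinodal k*).
    """
    if reverse_method not in ("retention", "upper_branch"):
        raise ValueError("reverse_method must be 'retention' or 'upper_branch'")
    grid = np.asarray(grid, dtype=float)
    forward = scan_parameter(spec, parameter, grid, branch="lower")
    bracket = (float(grid[0]), float(grid[-1]))
    fwd_rep = classify_transition(
        spec, parameter, bracket, onset_eps, jump_delta, bisection_tol
    )
    if reverse_method == "upper_branch":
        reverse = scan_parameter(spec, parameter, grid, branch="upper")
        rev_rep = classify_transition(
            spec, parameter, bracket, onset_eps, jump_delta, bisection_tol,
            solver=lambda v: _p_inf_at(spec, parameter, v, "upper"),
        )
    else:
        points = [
            _retention_point(spec, parameter, v, n, replicates, seed) for v in grid
        ]
        reverse = ScanResult(
            parameter=parameter,
            grid=grid,
            Pa_lower=np.array([p[0] for p in points]),
            P_inf_lower=np.array([p[1] for p in points]),
        )
        rev_rep = classify_transition(
            spec, parameter, bracket,
            onset_eps=SIM_ONSET_EPS,
            jump_delta=SIM_JUMP_DELTA,
            bisection_tol=SIM_BISECTION_TOL,
            coarse_points=min(len(grid), 17),
            solver=lambda v: _retention_point(spec, parameter, v, n, replicates, seed)[1],
        )
    return HysteresisResult(
        forward=forward, reverse=reverse,
        forward_report=fwd_rep, reverse_report=rev_rep,
    )


def table2_taxonomy(
    grids: Optional[dict[str, list[dict]]] = None,
) -> dict[str, set[str]]:
    """Observed transition types per network family on coarse scan grids.

    Returns, for each of directed/undirected ER and SF, the set of
    transition types the classifier finds across the family's desk-scale
    grid: ER families scan mean degree at several (m, q) settings; SF
    families scan the seed fraction q at several exponents γ (the hub-
    dominated first-order regime sits at small γ, the hybrid regime at
    intermediate γ, and the continuous regime at large γ).  ``grids``
    may override the defaults; each entry carries its own ModelSpec
    keywords plus ``parameter`` and ``bracket``.
    """
    if grids is None:
        grids = default_taxonomy_grids()
    observed: dict[str, set[str]] = {}
    for name, entries in grids.items():
        types: set[str] = set()
        for cfg in entries:
            cfg = dict(cfg)
            parameter = cfg.pop("parameter")
            bracket = cfg.pop("bracket")
            spec = ModelSpec(**cfg)
            rep = classify_transition(spec, parameter, bracket)
            types.add(rep.type)
        observed[name] = types - {"none"}
    return observed


def default_taxonomy_grids() -> dict[str, list[dict]]:
    """Desk-scale (coarsened) grids covering the four network families."""

    def er(directed: bool) -> list[dict]:
        base = {"family": "er", "directed": directed, "mean_degree": 1.0,
                "parameter": "mean_degree", "bracket": (0.2, 12.0)}
        return [
            {**base, "m": 2, "q": 0.05},
            {**base, "m": 2, "q": 0.45},
            {**base, "m": 3, "q": 0.19},
        ]

    def sf(directed: bool) -> list[dict]:
        base = {"family": "sf", "directed": directed, "m": 2, "q": 0.1,
                "parameter": "q"}
        if directed:
            return [
                {**base, "gamma": 1.6, "bracket": (0.0005, 0.02)},
                {**base, "gamma": 1.9, "bracket": (0.001, 0.05)},
                {**base, "gamma": 3.0, "bracket": (0.02, 0.9)},
            ]
        return [
            {**base, "gamma": 2.05, "bracket": (0.0005, 0.01)},
            {**base, "gamma": 2.3, "bracket": (0.0005, 0.01)},
            {**base, "gamma": 3.0, "bracket": (0.02, 0.9)},
        ]

    return {
        "directed_er": er(True),
        "undirected_er": er(False),
        "directed_sf": sf(True),
        "undirected_sf": sf(False),
    }


def write_scan_csv(scan: ScanResult, sink: IO[str]) -> None:
    """CSV dump with columns parameter, value, branch, Pa, P_inf, converged."""
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(["parameter", "value", "branch", "Pa", "P_inf", "converged"])
    conv = (
        scan.converged
        if scan.converged is not None
        else np.ones(scan.grid.shape[0], dtype=bool)
    )
    for i, v in enumerate(scan.grid):
        writer.writerow([
            scan.parameter, repr(float(v)), "lower",
            repr(float(scan.Pa_lower[i])), repr(float(scan.P_inf_lower[i])),
            bool(conv[i]),
        ])
    if scan.P_inf_upper is not None:
        for i, v in enumerate(scan.grid):
            writer.writerow([
                scan.parameter, repr(float(v)), "upper",
                repr(float(scan.Pa_upper[i])), repr(float(scan.P_inf_upper[i])),
                True,
            ])
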