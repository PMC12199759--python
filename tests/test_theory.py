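import json
import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from growperc import (
    binomial_term,
    er_joint,
    h_closed,
    poisson_degree_distribution,
    powerlaw_degree_distribution,
    solve_directed,
    solve_undirected,
)
from growperc.theory import gcc_term_high, gcc_term_low, solution_to_json

from oracles import (
    binom_pmf_enumerated,
    directed_stage1_literal,
    gcc_high_explicit_sum,
    gcc_low_explicit_sum,
    h_explicit_sum,
    undirected_stage1_literal,
)


class TestBinomialTerm:
    def test_symmetric_case(self):
        assert binomial_term(0.5, 2, 1) == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("p,n", [(0.3, 7), (0.9, 4), (0.01, 12)])
    def test_normalization(self, p, n):
        assert sum(binomial_term(p, n, s) for s in range(n + 1)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_exhaustive_enumeration(self):
        for p, n, s in [(0.3, 8, 3), (0.7, 10, 7), (0.5, 9, 0)]:
            assert binomial_term(p, n, s) == pytest.approx(
                binom_pmf_enumerated(p, n, s), abs=1e-12
            )

    def test_large_n_stability(self):
        # log-space evaluation keeps extreme tails finite and accurate
        val = binomial_term(0.3, 2000, 700)
        assert val == pytest.approx(stats.binom.pmf(700, 2000, 0.3), rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_term(0.5, 3, 4)
        with pytest.raises(ValueError):
            binomial_term(1.5, 3, 1)


class TestClosedForms:
    def test_h_zero_when_no_downstream_connection(self):
        for y in (0.0, 0.2, 0.9):
            assert h_closed(y, 0.0, 0.0, 5) == pytest.approx(0.0, abs=1e-14)

    def test_h_zero_neighborhood(self):
        assert h_closed(0.3, 0.2, 0.1, 0) == 0.0

    def test_h_equals_explicit_t_sum(self, rng):
        for _ in range(250):
            k = int(rng.integers(1, 13))
            y = float(rng.uniform(0.05, 0.95))
            yi = float(rng.uniform(0, y))
            xi = float(rng.uniform(yi, min(1.0, yi + (1 - y))))
            assert h_closed(y, xi, yi, k) == pytest.approx(
                h_explicit_sum(y, xi, yi, k), abs=1e-10
            )

    def _random_gcc_args(self, rng):
        xt = float(rng.uniform(0.1, 0.95))
        yt = float(rng.uniform(0.01, xt))
        beta = float(rng.uniform(0, xt))
        gamma_v = float(rng.uniform(max(0.0, beta - (xt - yt)), min(yt, beta)))
        alpha = float(rng.uniform(beta, min(1.0, beta + (1 - xt))))
        return xt, yt, alpha, beta, gamma_v

    def test_gcc_low_term_equals_explicit_t_sum(self, rng):
        for _ in range(250):
            xt, yt, alpha, beta, gamma_v = self._random_gcc_args(rng)
            s = int(rng.integers(1, 12))
            assert gcc_term_low(s, xt, yt, beta, gamma_v) == pytest.approx(
                gcc_low_explicit_sum(s, xt, yt, beta, gamma_v), abs=1e-10
            )

    def test_gcc_high_term_equals_explicit_t_sum(self, rng):
        for _ in range(250):
            xt, yt, alpha, beta, gamma_v = self._random_gcc_args(rng)
            k = int(rng.integers(2, 13))
            s = int(rng.integers(1, k))
            assert gcc_term_high(s, k, xt, yt, alpha, beta, gamma_v) == pytest.approx(
                gcc_high_explicit_sum(s, k, xt, yt, alpha, beta, gamma_v), abs=1e-10
            )


class TestUndirectedSolver:
    def test_no_seeds_no_activity(self):
        sol = solve_undirected(poisson_degree_distribution(2.0), q=0.0, m=2)
        assert sol.x_t == sol.y_t == sol.Pa_hat == sol.P_inf == 0.0

    @pytest.mark.parametrize("mean", [1.5, 2.0, 3.0])
    def test_full_seeding_recovers_classical_giant_component(self, mean):
        sol = solve_undirected(poisson_degree_distribution(mean), q=1.0, m=2)
        root = brentq(lambda S: S - (1 - np.exp(-mean * S)), 1e-12, 1.0)
        assert sol.Pa_hat == pytest.approx(1.0, abs=1e-12)
        assert sol.P_inf == pytest.approx(root, abs=1e-6)

    def test_agrees_with_literal_equation_iteration(self):
        dist = poisson_degree_distribution(2.5, tail_tolerance=1e-8)
        q, m = 0.25, 2
        xt, yt = q, 0.0
        for _ in range(3000):
            xt, yt = undirected_stage1_literal(dist.support, dist.mass, q, m, xt, yt)
        sol = solve_undirected(dist, q=q, m=m)
        assert sol.x_t == pytest.approx(xt, abs=1e-8)
        assert sol.y_t == pytest.approx(yt, abs=1e-8)

    def test_literal_lower_branch_iteration_is_monotone(self):
        dist = poisson_degree_distribution(3.0, tail_tolerance=1e-8)
        xt, yt = 0.2, 0.0
        for _ in range(200):
            xt_new, yt_new = undirected_stage1_literal(
                dist.support, dist.mass, 0.2, 2, xt, yt
            )
            assert xt_new >= xt - 1e-15 and yt_new >= yt - 1e-15
            xt, yt = xt_new, yt_new

    def test_solution_invariants(self):
        sol = solve_undirected(poisson_degree_distribution(3.0), q=0.3, m=2)
        assert 0 <= sol.y_t <= sol.x_t <= 1
        assert sol.gamma_v <= sol.beta + 1e-12 <= sol.alpha + 2e-12
        assert sol.Pa_hat >= sol.q
        assert sol.P_inf <= sol.Pa_hat + 1e-9
        assert sol.converged

    def test_lower_branch_monotone_in_q_and_mean_degree(self):
        previous = -1.0
        for q in (0.1, 0.2, 0.35, 0.5, 0.8):
            sol = solve_undirected(poisson_degree_distribution(2.5), q=q, m=2)
            assert sol.P_inf >= previous - 1e-10
            previous = sol.P_inf
        previous = -1.0
        for mean in (0.5, 1.5, 2.5, 4.0, 6.0):
            sol = solve_undirected(poisson_degree_distribution(mean), q=0.3, m=2)
            assert sol.P_inf >= previous - 1e-10
            previous = sol.P_inf

    def test_upper_branch_dominates_lower(self):
        for mean in (2.0, 3.2, 3.4, 5.0):
            dist = poisson_degree_distribution(mean)
            lo = solve_undirected(dist, q=0.19, m=3, branch="lower")
            hi = solve_undirected(dist, q=0.19, m=3, branch="upper")
            assert hi.x_t >= lo.x_t - 1e-10
            assert hi.y_t >= lo.y_t - 1e-10
            assert hi.P_inf >= lo.P_inf - 1e-10

    def test_acceleration_matches_plain_iteration(self):
        dist = powerlaw_degree_distribution(2.5, 1, 100)
        fast = solve_undirected(dist, q=0.01, m=2)
        slow = solve_undirected(
            dist, q=0.01, m=2, accelerate=False, tol=1e-12, max_iter=500_000
        )
        assert fast.Pa_hat == pytest.approx(slow.Pa_hat, abs=1e-9)
        assert fast.P_inf == pytest.approx(slow.P_inf, abs=1e-7)


class TestDirectedSolver:
    def test_no_seeds_no_activity(self):
        sol = solve_directed(er_joint(2.0), q=0.0, m=2)
        assert sol.x == sol.y == sol.Pa == sol.P_inf == 0.0

    def test_full_seeding_recovers_classical_gout(self):
        # at q=1 the GOUT messages reduce to classical directed percolation,
        # which for Poisson in-degrees shares the undirected root equation
        mean = 2.0
        sol = solve_directed(er_joint(mean), q=1.0, m=3)
        root = brentq(lambda S: S - (1 - np.exp(-mean * S)), 1e-12, 1.0)
        assert sol.Pa == pytest.approx(1.0, abs=1e-12)
        assert sol.P_inf == pytest.approx(root, abs=1e-6)

    def test_agrees_with_literal_equation_iteration(self):
        dist = er_joint(1.8, tail_tolerance=1e-7)
        q, m = 0.3, 2
        x, y = q, 0.0
        for _ in range(2000):
            x, y = directed_stage1_literal(dist.support, dist.mass, q, m, x, y)
        sol = solve_directed(dist, q=q, m=m)
        assert sol.x == pytest.approx(x, abs=1e-8)
        assert sol.y == pytest.approx(y, abs=1e-8)

    def test_solution_invariants(self):
        sol = solve_directed(er_joint(3.0), q=0.3, m=2)
        assert 0 <= sol.y <= sol.x <= 1
        assert sol.y_inf <= sol.y + 1e-12
        assert sol.y_inf <= sol.x_inf + 1e-12
        assert sol.Pa >= sol.q
        assert sol.P_inf <= sol.Pa + 1e-9

    def test_er_active_fraction_symmetry_with_undirected(self):
        """Directed and undirected ER networks share the same final
        active fraction at matched (q, m, mean degree)."""
        for m in (2, 3):
            for q in (0.1, 0.4):
                for mean in (1.5, 3.0):
                    und = solve_undirected(
                        poisson_degree_distribution(mean), q=q, m=m
                    )
                    dir_ = solve_directed(er_joint(mean), q=q, m=m)
                    assert abs(und.Pa_hat - dir_.Pa) < 1e-8

    def test_branch_argument_validated(self):
        with pytest.raises(ValueError):
            solve_directed(er_joint(2.0), q=0.5, m=2, branch="middle")


class TestErJoint:
    def test_marginals_and_symmetry(self):
        joint = er_joint(1.5)
        marg = poisson_degree_distribution(1.5)
        np.testing.assert_allclose(joint.in_marginal().mass, marg.mass, atol=1e-12)
        assert abs(joint.mean_in - joint.mean_out) < 1e-12
        assert abs(joint.mass.sum() - 1.0) < 1e-12


def test_solution_serializes_to_json():
    sol = solve_undirected(poisson_degree_distribution(2.0), q=0.5, m=2)
    record = json.loads(solution_to_json(sol))
    assert record["q"] == 0.5 and record["converged"] is True
    assert math.isclose(record["Pa_hat"], sol.Pa_hat)
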