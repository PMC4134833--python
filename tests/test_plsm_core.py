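"""Solver core: ansatz calculus, elimination, objective and minimizers."""

import numpy as np
import pytest
import sympy as sp

from plsm.dde_problem import DerivativeTerm, ArgumentMap
from plsm.plsm_core import (
    ObjectiveSpec,
    PolynomialCandidate,
    SolverError,
    build_constraint_elimination,
    constraint_violation,
    degree_search,
    eval_delayed,
    minimize_objective,
    objective_J,
    objective_gradient,
    objective_symbolic,
    poly_derivative,
    residual_eval,
    solve_linear,
)
from plsm.reference_oracle import manufactured_problem

RICCATI = PolynomialCandidate.from_coeffs([-2.0, -1.0, 1.0])  # t^2 - t - 2


class TestPolyCalculus:
    @pytest.mark.parametrize(
        "coeffs, order, expected",
        [
            ([-2, -1, 1], 1, [-1, 2]),
            ([7.0], 1, [0.0]),  # constant
            ([0, 0, 1], 3, [0.0]),  # order above degree
            ([1, 2, 3, 4], 2, [6, 24]),
        ],
    )
    def test_derivative_by_power_rule(self, coeffs, order, expected):
        np.testing.assert_allclose(poly_derivative(coeffs, order), expected)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            poly_derivative([1, 2], -1)

    @pytest.mark.parametrize(
        "order, arg, t, expected",
        [
            (0, (-1.0, 1.0), 0.0, 0.0),  # s^2-s-2 at s=-1
            (1, (-2.0, 1.0), 0.0, -5.0),  # 2s-1 at s=-2
            (0, (0.0, 1.0), 0.4, RICCATI(0.4)),  # identity argument
        ],
    )
    def test_eval_delayed(self, order, arg, t, expected):
        term = DerivativeTerm(order, ArgumentMap(arg))
        assert eval_delayed(RICCATI, term, t) == pytest.approx(expected, abs=1e-14)


class TestResidualEval:
    def test_exact_candidate_gives_zero_residual(self, problems):
        assert residual_eval(problems["app1"], RICCATI, 0.37) == pytest.approx(0, abs=1e-12)
        exact2 = PolynomialCandidate.from_coeffs([0, 0, 1])
        for t in (0.0, 0.31, 1.0):
            assert residual_eval(problems["app2"], exact2, t) == pytest.approx(0, abs=1e-13)

    def test_zero_candidate_residual_value(self, problems):
        # R reduces to (c2 - 1)(1 - t - t^2); at c2 = 0, t = 0 that is -1
        zero = PolynomialCandidate.from_coeffs([0, 0, 0])
        assert residual_eval(problems["app2"], zero, 0.0) == pytest.approx(-1.0, abs=1e-14)


class TestConstraintElimination:
    def test_riccati_fixes_constant_term(self, problems):
        elim = build_constraint_elimination(problems["app1"], 2)
        assert elim.eliminated_indices == (0,)
        assert elim.map_offset[0] == pytest.approx(-2.0)
        assert elim.map_matrix[0] == pytest.approx([0.0, 0.0])  # c0 independent of free

    def test_neutral_problem_fixes_two_terms(self, problems):
        elim = build_constraint_elimination(problems["app2"], 2)
        c = elim.full_coeffs([5.0])
        np.testing.assert_allclose(c, [0.0, 0.0, 5.0], atol=1e-14)

    def test_pantograph_coupled_conditions(self, problems):
        # 3c0 + 6c1 = 2 and -2c0 + c1 = -1/2  =>  c0 = 1/3, c1 = 1/6
        elim = build_constraint_elimination(problems["app3"], 5)
        c = elim.full_coeffs(np.zeros(4))
        assert c[0] == pytest.approx(1 / 3, rel=1e-13)
        assert c[1] == pytest.approx(1 / 6, rel=1e-13)

    def test_degree_below_order_rejected(self, problems):
        with pytest.raises(SolverError):
            build_constraint_elimination(problems["app3"], 1)

    def test_singular_conditions_rejected(self, problems):
        import dataclasses
        from plsm.dde_problem import InitialConditionSet

        p = problems["app2"]
        bad = dataclasses.replace(
            p,
            conditions=InitialConditionSet(0.0, ((1.0, 0.0), (1.0, 0.0)), (0.0, 1.0)),
        )
        with pytest.raises(SolverError, match="singular"):
            build_constraint_elimination(bad, 4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parametrization_satisfies_conditions(self, problems, seed):
        rng = np.random.default_rng(seed)
        for prob, m in [(problems["app3"], 5), (problems["app4"], 9)]:
            elim = build_constraint_elimination(prob, m)
            cand = PolynomialCandidate.from_coeffs(
                elim.full_coeffs(rng.standard_normal(elim.n_free))
            )
            assert constraint_violation(prob, cand) < 1e-12

    def test_offcenter_interval_couples_all_coefficients(self):
        # conditions at alpha = 0.5: eliminated coefficients must depend on free ones
        prob, _ = manufactured_problem(3, order=1, degree=3, interval=(0.5, 1.5))
        elim = build_constraint_elimination(prob, 4)
        assert np.any(elim.map_matrix[0] != 0.0)
        rng = np.random.default_rng(0)
        cand = PolynomialCandidate.from_coeffs(
            elim.full_coeffs(rng.standard_normal(elim.n_free))
        )
        assert constraint_violation(prob, cand) < 1e-12


class TestObjective:
    def test_quadratic_objective_values(self, problems):
        elim = build_constraint_elimination(problems["app2"], 2)
        assert objective_J(problems["app2"], elim, [0.0]) == pytest.approx(11 / 30, rel=1e-13)
        assert objective_J(problems["app2"], elim, [1.0]) == pytest.approx(0.0, abs=1e-28)

    def test_symbolic_objective_closed_form(self, problems):
        J, (c2,) = objective_symbolic(problems["app2"], 2)
        expected = sp.expand(sp.Rational(11, 30) * (c2 - 1) ** 2)
        assert sp.simplify(J - expected) == 0

    @pytest.mark.parametrize("ident, m", [("app1", 2), ("app2", 3)])
    def test_symbolic_and_quadrature_modes_agree(self, problems, ident, m):
        prob = problems[ident]
        elim = build_constraint_elimination(prob, m)
        rng = np.random.default_rng(7)
        for _ in range(3):
            f = rng.standard_normal(elim.n_free)
            Jq = objective_J(prob, elim, f, ObjectiveSpec(mode="gauss-quadrature"))
            Js = objective_J(prob, elim, f, ObjectiveSpec(mode="symbolic-exact"))
            assert Jq == pytest.approx(Js, rel=1e-12, abs=1e-20)

    def test_gradient_vanishes_at_published_minimizers(self, problems):
        elim1 = build_constraint_elimination(problems["app1"], 2)
        g1 = objective_gradient(problems["app1"], elim1, [-1.0, 1.0])
        np.testing.assert_allclose(g1, 0.0, atol=1e-12)
        elim2 = build_constraint_elimination(problems["app2"], 2)
        g2 = objective_gradient(problems["app2"], elim2, [1.0])
        np.testing.assert_allclose(g2, 0.0, atol=1e-13)

    def test_gradient_matches_central_differences(self):
        prob, _ = manufactured_problem(11, order=1, degree=3, nonlinear=True)
        elim = build_constraint_elimination(prob, 4)
        rng = np.random.default_rng(4)
        f = rng.standard_normal(elim.n_free)
        g = objective_gradient(prob, elim, f)
        h = 1e-6
        for k in range(elim.n_free):
            e = np.zeros(elim.n_free)
            e[k] = h
            fd = (objective_J(prob, elim, f + e) - objective_J(prob, elim, f - e)) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-6, abs=1e-8)


class TestSolvers:
    def test_linear_solver_recovers_exact_neutral_solution(self, bench):
        r = bench("app2").result
        np.testing.assert_allclose(r.polynomial.coeffs, [0, 0, 1], atol=1e-10)
        assert r.status == "converged"

    def test_linear_exact_polynomial_in_span_gives_tiny_objective(self):
        prob, coeffs = manufactured_problem(5, order=1, degree=3, nonlinear=False)
        r = solve_linear(prob, 4)
        assert r.objective_value < 1e-20
        np.testing.assert_allclose(r.polynomial.coeffs[:4], coeffs, atol=1e-8)

    def test_multistart_recovers_riccati_exact_solution(self, bench):
        r = bench("app1").result
        np.testing.assert_allclose(r.polynomial.coeffs, [-2, -1, 1], atol=1e-8)
        assert r.objective_value < 1e-16

    def test_minimize_dispatches_linear_problems_to_direct_solve(self, problems):
        direct = solve_linear(problems["app6"], 5)
        via_min = minimize_objective(problems["app6"], 5)
        np.testing.assert_allclose(
            via_min.polynomial.coeffs, direct.polynomial.coeffs, rtol=0, atol=1e-12
        )

    @pytest.mark.parametrize("seed", [2, 9])
    def test_nonlinear_recovery_of_manufactured_polynomial(self, seed):
        prob, coeffs = manufactured_problem(seed, order=1, degree=3, nonlinear=True)
        r = minimize_objective(prob, 3, seed=seed)
        np.testing.assert_allclose(r.polynomial.coeffs, coeffs, atol=1e-8)

    def test_truncated_span_cannot_reach_zero_objective(self):
        prob, _ = manufactured_problem(0, order=1, degree=3)
        r = minimize_objective(prob, 2)  # exact solution has degree 3
        assert r.objective_value > 1e-8


class TestDegreeSearch:
    def test_stops_at_first_degree_reaching_epsilon(self, problems):
        r, trace = degree_search(problems["app2"], 1e-8, 3, 6)
        assert trace[0][0] == 3 and len(trace) == 1
        assert r.max_residual < 1e-8

    def test_pantograph_terminates_by_degree_nine(self, problems):
        r, trace = degree_search(problems["app4"], 1e-6, 4, 9)
        assert r.max_residual < 1e-6
        assert trace[-1][0] <= 9

    def test_objective_nonincreasing_along_sweep(self, problems):
        _, trace = degree_search(problems["app5"], 1e-14, 2, 6, starts=3)
        Js = [J for _, J, _ in trace]
        assert all(b <= a + 1e-12 for a, b in zip(Js, Js[1:]))
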