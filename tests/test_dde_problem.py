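"""Problem parsing, forcing derivation and validation diagnostics."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from plsm.dde_problem import (
    ArgumentMap,
    ProblemError,
    T,
    derive_forcing,
    parse_expression,
    parse_problem,
    serialize_problem,
    substitute_function,
    validate_problem,
)

APP2_TOML = """
order = 2
interval = [0.0, 1.0]
residual = "x2(t) - 3/4*x0(t) - x0(t/2) - x1(t/2) - 1/2*x2(t/2) + t^2 + t - 1"
exact = "t^2"
[[conditions]]
coeffs = [1.0, 0.0]
value = 0.0
[[conditions]]
coeffs = [0.0, 1.0]
value = 0.0
"""


class TestParsing:
    def test_app2_structure(self):
        p = parse_problem(APP2_TOML)
        assert p.order == 2
        assert p.interval == (0.0, 1.0)
        args = {t.argument.poly_coeffs for t in p.derivative_terms()}
        assert args == {(0.0, 1.0), (0.0, 0.5)}  # t and t/2

    def test_condition_count_mismatch(self):
        bad = APP2_TOML.replace('[[conditions]]\ncoeffs = [0.0, 1.0]\nvalue = 0.0', "")
        with pytest.raises(ProblemError, match="condition count mismatch"):
            parse_problem(bad)

    def test_derivative_order_above_n_rejected(self):
        with pytest.raises(ProblemError, match="exceeds problem order"):
            parse_expression("x3(t) + x0(t)", max_order=2)

    def test_empty_interval_rejected(self):
        with pytest.raises(ProblemError, match="empty"):
            parse_problem(APP2_TOML.replace("[0.0, 1.0]", "[1.0, 1.0]"))

    def test_malformed_expression(self):
        with pytest.raises(ProblemError, match="malformed"):
            parse_expression("x0(t -")

    def test_nonpolynomial_delay_rejected(self):
        with pytest.raises(ProblemError, match="not polynomial"):
            parse_expression("x0(sin(t))")

    def test_exact_attached(self, problems):
        # the order-3 pantograph benchmark carries exp(-t) as exact solution
        p = problems["app4"]
        fn = sp.lambdify(T, p.exact)
        assert fn(0.7) == pytest.approx(np.exp(-0.7), rel=1e-14)

    @pytest.mark.parametrize("ident", ["app1", "app2", "app3", "app4", "app5", "app6"])
    def test_serialize_round_trip(self, problems, ident):
        p = problems[ident]
        q = parse_problem(serialize_problem(p))
        assert p.equals(q)


class TestDeriveForcing:
    def grid_residual(self, residual, exact):
        fn = sp.lambdify(T, substitute_function(residual, exact), "numpy")
        g = np.linspace(0, 1, 101)
        return np.max(np.abs(np.broadcast_to(np.asarray(fn(g), float), g.shape)))

    def test_riccati_structure_polynomial_forcing(self):
        x0, x1 = sp.Function("x0"), sp.Function("x1")
        structural = x1(T - 2) - T**2 * x0(2 * T - 3) - x0(T - 1) ** 2
        exact = T**2 - T - 2
        residual = derive_forcing(structural, exact, 1)
        g = residual - structural
        assert g.is_polynomial(T)
        # independent symbolic expansion of -structural[x := exact]
        expected = sp.expand(-substitute_function(structural, exact))
        assert sp.expand(g - expected) == 0
        assert self.grid_residual(residual, exact) < 1e-10

    def test_zero_exact_gives_negated_structural_terms(self):
        x0 = sp.Function("x0")
        structural = sp.Function("x1")(T) + x0(T / 2) + 3
        residual = derive_forcing(structural, sp.Integer(0), 1)
        assert sp.simplify(residual - structural + 3) == 0

    def test_pantograph_transcendental_forcing(self, problems):
        p = problems["app3"]  # forcing already derived at parse time
        assert self.grid_residual(p.residual, p.exact) < 1e-10

    @pytest.mark.parametrize("ident", ["app1", "app2", "app3", "app4"])
    def test_benchmarks_with_exact_have_zero_residual(self, problems, ident):
        p = problems[ident]
        fn = sp.lambdify(T, substitute_function(p.residual, p.exact), "numpy")
        g = np.linspace(*p.interval, 101)
        vals = np.broadcast_to(np.asarray(fn(g), float), g.shape)
        assert np.max(np.abs(vals)) < 1e-10


class TestValidate:
    def test_logistic_flags_argument_below_alpha(self, problems):
        report = validate_problem(problems["app5"])
        assert any("t - 0.1" in k or "-0.1 + t" in k
                   for k in report["arguments_outside_interval"])

    def test_neutral_benchmark_is_linear_in_coefficients(self, problems):
        assert validate_problem(problems["app2"])["linear_in_coefficients"]

    def test_squared_term_detected_as_nonlinear(self, problems):
        assert not validate_problem(problems["app1"])["linear_in_coefficients"]


@given(coeffs=st.lists(st.floats(-5, 5), min_size=1, max_size=4))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_argument_map_matches_sympy_evaluation(coeffs):
    amap = ArgumentMap(tuple(coeffs))
    expr = amap.as_sympy()
    for t in (-1.3, 0.0, 0.7, 2.0):
        assert amap(t) == pytest.approx(float(expr.subs(T, t)), rel=1e-12, abs=1e-12)
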