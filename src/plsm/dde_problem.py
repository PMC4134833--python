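"""Problem model for initial-value problems of delay differential equations.

A problem is the residual form

    F(x^(n)(h_n(t)), ..., x'(h_1(t)), x(h_0(t)), t) = 0,   t in [alpha, beta],

with single-point initial conditions  sum_i r_ij x^(i)(alpha) = s_j,
j = 1..n, where every delay argument h_k is a polynomial in t (constant
lags t - tau, proportional/pantograph lags q*t, or any other polynomial).

Residual expressions are sympy trees over the time variable ``t``, the
derivative-term symbols ``x0(arg) .. xn(arg)`` (``x{i}`` is the i-th
derivative of the unknown, ``x`` alone is an alias for ``x0``), arithmetic,
integer powers and the elementary functions sin, cos, exp.
"""

from __future__ import annotations

import io
import tomllib
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from sympy.core.function import AppliedUndef

__all__ = [
    "T",
    "ArgumentMap",
    "DerivativeTerm",
    "InitialConditionSet",
    "DDEProblem",
    "ProblemError",
    "x_func",
    "parse_expression",
    "parse_problem",
    "serialize_problem",
    "derive_forcing",
    "substitute_function",
    "validate_problem",
]

#: the independent (time) variable used in every expression
T = sp.Symbol("t")

_MAX_ORDER = 12


class ProblemError(ValueError):
    """Malformed or inconsistent problem definition."""


def x_func(order: int) -> sp.Function:
    """The undefined function standing for the ``order``-th derivative."""
    if order < 0:
        raise ProblemError(f"negative derivative order {order}")
    return sp.Function(f"x{order}")


_LOCALS = {"t": T, "x": x_func(0), "pi": sp.pi, "E": sp.E}
_LOCALS.update({f"x{i}": x_func(i) for i in range(_MAX_ORDER + 1)})
_ALLOWED_FUNCS = (sp.sin, sp.cos, sp.exp)


@dataclass(frozen=True)
class ArgumentMap:
    """A polynomial delay argument h(t), stored densely in ascending powers."""

    poly_coeffs: tuple[float, ...]

    def __post_init__(self):
        if len(self.poly_coeffs) == 0:
            object.__setattr__(self, "poly_coeffs", (0.0,))

    @property
    def degree(self) -> int:
        return len(self.poly_coeffs) - 1

    def __call__(self, t):
        return np.polynomial.polynomial.polyval(t, np.asarray(self.poly_coeffs))

    def as_sympy(self) -> sp.Expr:
        return sum(sp.Float(c) * T**k for k, c in enumerate(self.poly_coeffs))

    @classmethod
    def from_sympy(cls, expr: sp.Expr) -> "ArgumentMap":
        poly = sp.Poly(expr, T)
        coeffs = [float(c) for c in reversed(poly.all_coeffs())]
        return cls(tuple(coeffs))


@dataclass(frozen=True)
class DerivativeTerm:
    """One delayed derivative factor x^(i)(h(t)) appearing in the residual."""

    derivative_order: int
    argument: ArgumentMap


@dataclass(frozen=True)
class InitialConditionSet:
    """Conditions sum_i r_ij x^(i)(alpha) = s_j, one row per condition j."""

    point: float
    coeff_matrix: tuple[tuple[float, ...], ...]  # row j, column i
    values: tuple[float, ...]

    @property
    def n_conditions(self) -> int:
        return len(self.values)


@dataclass(eq=False)
class DDEProblem:
    order: int
    interval: tuple[float, float]
    residual: sp.Expr
    conditions: InitialConditionSet
    exact: sp.Expr | None = None
    name: str = ""

    def __post_init__(self):
        alpha, beta = self.interval
        if not beta > alpha:
            raise ProblemError(f"interval [{alpha}, {beta}] is empty")
        if self.conditions.n_conditions != self.order:
            raise ProblemError(
                "condition count mismatch: "
                f"{self.conditions.n_conditions} conditions for order {self.order}"
            )
        if abs(self.conditions.point - alpha) > 1e-14:
            raise ProblemError("conditions must be imposed at the left endpoint")
        for term in self.derivative_terms():
            if term.derivative_order > self.order:
                raise ProblemError(
                    f"derivative order {term.derivative_order} exceeds problem order"
                )

    def derivative_terms(self) -> list[DerivativeTerm]:
        """All distinct x^(i)(h(t)) terms of the residual."""
        terms = set()
        for f in self.residual.atoms(AppliedUndef):
            order = _func_order(f.func)
            terms.add(DerivativeTerm(order, ArgumentMap.from_sympy(f.args[0])))
        return sorted(terms, key=lambda d: (d.derivative_order, d.argument.poly_coeffs))

    def equals(self, other: "DDEProblem") -> bool:
        """Field-by-field structural equality (used by round-trip checks)."""
        return (
            self.order == other.order
            and self.interval == other.interval
            and sp.simplify(self.residual - other.residual) == 0
            and self.conditions == other.conditions
            and (
                (self.exact is None and other.exact is None)
                or (
                    self.exact is not None
                    and other.exact is not None
                    and sp.simplify(self.exact - other.exact) == 0
                )
            )
        )


def _func_order(func) -> int:
    name = func.__name__
    if not (name.startswith("x") and name[1:].isdigit()):
        raise ProblemError(f"unknown function '{name}' in residual")
    return int(name[1:])


def parse_expression(text: str, max_order: int | None = None) -> sp.Expr:
    """Parse an expression string in the ``x{i}(arg)`` grammar into sympy.

    ``^`` and ``**`` both denote integer powers. The grammar is closed over
    +, -, *, /, powers, sin, cos, exp, the constant pi and the variable t.
    """
    from sympy.parsing.sympy_parser import (
        convert_xor,
        parse_expr,
        standard_transformations,
    )

    try:
        expr = parse_expr(
            text,
            local_dict=_LOCALS,
            transformations=standard_transformations + (convert_xor,),
        )
    except Exception as err:  # sympy raises a zoo of exception types
        raise ProblemError(f"malformed expression {text!r}: {err}") from err
    _validate_expression(expr, max_order)
    return expr


def _validate_expression(expr: sp.Expr, max_order: int | None) -> None:
    for f in expr.atoms(AppliedUndef):
        order = _func_order(f.func)
        if max_order is not None and order > max_order:
            raise ProblemError(
                f"derivative order {order} in expression exceeds problem order {max_order}"
            )
        if len(f.args) != 1:
            raise ProblemError(f"{f} must have exactly one argument")
        if not f.args[0].is_polynomial(T):
            raise ProblemError(f"delay argument {f.args[0]} is not polynomial in t")
    for f in expr.atoms(sp.Function):
        if isinstance(f, AppliedUndef):
            continue
        if not isinstance(f, _ALLOWED_FUNCS):
            raise ProblemError(f"function {f.func} is outside the expression grammar")


def parse_problem(config_text: str) -> DDEProblem:
    """Build a validated :class:`DDEProblem` from a TOML problem definition.

    Keys: ``order``, ``interval = [a, b]``, ``residual`` (expression string),
    ``conditions`` (list of ``{coeffs = [r_0j, ...], value = s_j}``), and
    optionally ``exact`` (expression string), ``derive_forcing`` (boolean:
    interpret ``residual`` as the forcing-free structural part and derive the
    forcing term symbolically from ``exact``), and ``name``.
    """
    try:
        cfg = tomllib.loads(config_text)
    except tomllib.TOMLDecodeError as err:
        raise ProblemError(f"invalid TOML: {err}") from err

    try:
        order = int(cfg["order"])
        a, b = (float(v) for v in cfg["interval"])
        residual_text = cfg["residual"]
        conditions_cfg = cfg["conditions"]
    except (KeyError, TypeError, ValueError) as err:
        raise ProblemError(f"missing or malformed problem key: {err}") from err

    residual = parse_expression(residual_text, max_order=order)
    exact = None
    if "exact" in cfg:
        exact = parse_expression(cfg["exact"], max_order=0)
        if exact.atoms(AppliedUndef):
            raise ProblemError("exact solution must be an expression of t only")
    if cfg.get("derive_forcing", False):
        if exact is None:
            raise ProblemError("derive_forcing requires an exact solution")
        residual = derive_forcing(residual, exact, order, (a, b))

    rows, values = [], []
    for cond in conditions_cfg:
        coeffs = [float(c) for c in cond["coeffs"]]
        if len(coeffs) > order:
            raise ProblemError("condition references derivative of order >= n")
        coeffs += [0.0] * (order - len(coeffs))
        rows.append(tuple(coeffs))
        values.append(float(cond["value"]))

    conditions = InitialConditionSet(point=a, coeff_matrix=tuple(rows), values=tuple(values))
    return DDEProblem(
        order=order,
        interval=(a, b),
        residual=residual,
        conditions=conditions,
        exact=exact,
        name=str(cfg.get("name", "")),
    )


def serialize_problem(problem: DDEProblem) -> str:
    """Emit a TOML definition that :func:`parse_problem` parses back to an
    identical problem (the forcing term, if derived, is written explicitly)."""
    buf = io.StringIO()
    if problem.name:
        buf.write(f'name = "{problem.name}"\n')
    buf.write(f"order = {problem.order}\n")
    a, b = problem.interval
    buf.write(f"interval = [{a!r}, {b!r}]\n")
    buf.write(f'residual = "{sp.sstr(problem.residual, full_prec=True)}"\n')
    if problem.exact is not None:
        buf.write(f'exact = "{sp.sstr(problem.exact, full_prec=True)}"\n')
    for row, value in zip(problem.conditions.coeff_matrix, problem.conditions.values):
        coeffs = ", ".join(repr(c) for c in row)
        buf.write(f"[[conditions]]\ncoeffs = [{coeffs}]\nvalue = {value!r}\n")
    return buf.getvalue()


def substitute_function(expr: sp.Expr, solution: sp.Expr) -> sp.Expr:
    """Replace every x^(i)(h(t)) in ``expr`` by d^i solution/dt^i evaluated at h(t)."""

    def repl(f):
        order = _func_order(f.func)
        return sp.diff(solution, T, order).subs(T, f.args[0])

    return expr.replace(lambda e: isinstance(e, AppliedUndef), repl)


def derive_forcing(
    structural: sp.Expr,
    exact: sp.Expr,
    order: int,
    interval: tuple[float, float] = (0.0, 1.0),
    *,
    check_points: int = 101,
    tol: float = 1e-10,
) -> sp.Expr:
    """Manufacture the forcing term so that ``exact`` solves the equation.

    Returns ``structural + g(t)`` with ``g = -structural[x := exact]``; the
    residual of the returned expression vanishes identically at the exact
    solution, which is verified numerically on a uniform grid.
    """
    g = -substitute_function(structural, exact)
    try:
        g = sp.expand(g)
    except Exception:
        pass
    residual = structural + g
    check = substitute_function(residual, exact)
    fn = sp.lambdify(T, check, modules="numpy")
    grid = np.linspace(interval[0], interval[1], check_points)
    vals = np.asarray(fn(grid), dtype=float)
    vals = np.broadcast_to(vals, grid.shape)
    if not np.all(np.isfinite(vals)):
        raise ProblemError("derived forcing produced non-finite residual")
    worst = float(np.max(np.abs(vals)))
    if worst >= tol:
        raise ProblemError(
            f"derived forcing leaves residual {worst:.3e} at the exact solution"
        )
    return residual


def validate_problem(problem: DDEProblem, *, rng_seed: int = 0) -> dict:
    """Pure diagnostic report on a problem (never raises).

    Reports the range of every delay argument over [alpha, beta] and flags
    arguments leaving the interval (those are evaluated by analytic
    continuation of the global polynomial ansatz), whether the residual is
    affine in the ansatz coefficients (probed numerically), and whether an
    exact solution is attached.
    """
    alpha, beta = problem.interval
    grid = np.linspace(alpha, beta, 513)
    ranges: dict[str, tuple[float, float]] = {}
    outside: list[str] = []
    for term in problem.derivative_terms():
        h = term.argument(grid)
        h = np.broadcast_to(np.asarray(h, dtype=float), grid.shape)
        lo, hi = float(h.min()), float(h.max())
        key = f"x{term.derivative_order}({sp.sstr(term.argument.as_sympy())})"
        ranges[key] = (lo, hi)
        if lo < alpha - 1e-12 or hi > beta + 1e-12:
            outside.append(key)
    return {
        "argument_ranges": ranges,
        "arguments_outside_interval": outside,
        "linear_in_coefficients": _probe_affine(problem, rng_seed),
        "has_exact": problem.exact is not None,
    }


def _probe_affine(problem: DDEProblem, seed: int, *, pairs: int = 8) -> bool:
    """Numerically test whether the residual is affine in the coefficients.

    An expression R(c) is affine iff R(a) + R(b) - R(a + b) - R(0) == 0 for
    all coefficient vectors a, b; this is probed at random points.
    """
    from .plsm_core import ResidualEvaluator

    m = problem.order + 1
    ev = ResidualEvaluator.for_problem(problem, m)
    rng = np.random.default_rng(seed)
    ts = rng.uniform(*problem.interval, size=pairs)
    zero = np.zeros(m + 1)
    r0 = ev.value(ts, zero)
    for _ in range(pairs):
        ca = rng.standard_normal(m + 1)
        cb = rng.standard_normal(m + 1)
        lhs = ev.value(ts, ca) + ev.value(ts, cb) - ev.value(ts, ca + cb) - r0
        scale = 1.0 + np.max(np.abs(ev.value(ts, ca))) + np.max(np.abs(r0))
        if np.max(np.abs(lhs)) > 1e-8 * scale:
            return False
    return True
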