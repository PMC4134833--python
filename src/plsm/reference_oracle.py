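"""Independent numerical reference for validating polynomial solutions.

Two validation devices live here:

* a classical method-of-steps integrator (fixed-step RK4 with cubic-Hermite
  dense output for delayed lookups, restarting at constant-lag multiples),
  driven by an explicit history function on t <= alpha — deliberately a
  different solution concept from the solver's global-polynomial
  continuation, so the two can disagree near alpha when the true solution
  has derivative discontinuities;
* a manufactured-problem generator: a random polynomial is declared the
  exact solution and a consistent forcing term is derived symbolically,
  yielding delay problems with known closed-form answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy as sp
from sympy.core.function import AppliedUndef

from .dde_problem import (
    ArgumentMap,
    DDEProblem,
    InitialConditionSet,
    ProblemError,
    T,
    _func_order,
    derive_forcing,
    x_func,
)

__all__ = [
    "HistoryFunction",
    "FirstOrderDelaySystem",
    "DenseSolution",
    "NeutralEquationError",
    "to_first_order",
    "integrate",
    "manufactured_problem",
]


class NeutralEquationError(ValueError):
    """The highest derivative appears only with a delayed argument; the
    method-of-steps oracle declines such (neutral/advanced) equations."""


@dataclass(frozen=True)
class HistoryFunction:
    """Solution history x(t) for t <= alpha, given as an expression of t."""

    expression: sp.Expr

    @classmethod
    def make(cls, expr) -> "HistoryFunction":
        return cls(sp.sympify(expr))

    def derivative_fn(self, order: int):
        d = sp.diff(self.expression, T, order)
        fn = sp.lambdify(T, d, modules="numpy")
        return lambda t: float(fn(float(t)))


@dataclass
class FirstOrderDelaySystem:
    """Companion system y' = f(t, y, delayed values), y = (x, x', ..., x^(n-1))."""

    dimension: int
    rhs: callable  # rhs(t, y, u) -> float, the n-th derivative
    delayed_terms: tuple  # ((derivative order i, ArgumentMap h), ...)
    history: HistoryFunction
    alpha: float
    initial_state: np.ndarray

    def history_derivative(self, order: int, t: float) -> float:
        return self._hist_fns[order](t)

    def __post_init__(self):
        self._hist_fns = [
            self.history.derivative_fn(i) for i in range(self.dimension)
        ]


def to_first_order(
    problem: DDEProblem,
    history=None,
    initial_state=None,
) -> FirstOrderDelaySystem:
    """Reduce an order-n problem to an explicit companion system.

    The residual must be symbolically solvable for the undelayed highest
    derivative x^(n)(t); equations where the highest derivative occurs only
    at a delayed argument raise :class:`NeutralEquationError`.

    ``history`` defaults to the problem's exact solution when one is
    attached; the initial state defaults to the history derivatives at
    alpha.
    """
    n = problem.order
    alpha = problem.interval[0]
    xn = x_func(n)

    top_terms = [f for f in problem.residual.atoms(AppliedUndef) if _func_order(f.func) == n]
    if not any(f.args[0] == T for f in top_terms):
        raise NeutralEquationError(
            "highest derivative never appears with the undelayed argument t"
        )
    if any(f.args[0] != T for f in top_terms):
        raise NeutralEquationError(
            "highest derivative appears with a delayed argument (neutral form)"
        )

    sols = sp.solve(problem.residual, xn(T), dict=False)
    if len(sols) != 1:
        raise NeutralEquationError(
            f"cannot solve residual uniquely for x^({n})(t) ({len(sols)} branches)"
        )
    rhs_expr = sols[0]

    ysyms = sp.symbols(f"y0:{n}")
    delayed: list[tuple[int, ArgumentMap]] = []
    usyms: list[sp.Symbol] = []

    def repl(f):
        order = _func_order(f.func)
        h = f.args[0]
        if h == T:
            return ysyms[order]
        u = sp.Symbol(f"u{len(usyms)}")
        usyms.append(u)
        delayed.append((order, ArgumentMap.from_sympy(h)))
        return u

    rhs_expr = rhs_expr.replace(lambda e: isinstance(e, AppliedUndef), repl)
    rhs_fn = sp.lambdify((T, *ysyms, *usyms), rhs_expr, modules="numpy")

    if history is None:
        if problem.exact is None:
            raise ProblemError("no history function given and no exact solution attached")
        history = problem.exact
    hist = history if isinstance(history, HistoryFunction) else HistoryFunction.make(history)

    if initial_state is None:
        fns = [hist.derivative_fn(i) for i in range(n)]
        initial_state = np.array([fn(alpha) for fn in fns])
    else:
        initial_state = np.asarray(initial_state, dtype=float)

    def rhs(t, y, u):
        return float(rhs_fn(t, *y, *u))

    return FirstOrderDelaySystem(
        dimension=n,
        rhs=rhs,
        delayed_terms=tuple(delayed),
        history=hist,
        alpha=alpha,
        initial_state=initial_state,
    )


@dataclass
class DenseSolution:
    """Piecewise cubic-Hermite representation of an integrated trajectory."""

    ts: np.ndarray  # (N,)
    ys: np.ndarray  # (N, d): x, x', ..., x^(d-1)
    fs: np.ndarray  # (N, d): time derivative of ys at the nodes

    @property
    def t_end(self) -> float:
        return float(self.ts[-1])

    def component(self, s: float, i: int = 0) -> float:
        """Hermite-interpolated value of x^(i) at s within the range."""
        k = int(np.searchsorted(self.ts, s, side="right")) - 1
        k = min(max(k, 0), len(self.ts) - 2)
        t0, t1 = self.ts[k], self.ts[k + 1]
        h = t1 - t0
        th = (s - t0) / h
        y0, y1 = self.ys[k, i], self.ys[k + 1, i]
        f0, f1 = self.fs[k, i], self.fs[k + 1, i]
        h00 = (1 + 2 * th) * (1 - th) ** 2
        h10 = th * (1 - th) ** 2
        h01 = th * th * (3 - 2 * th)
        h11 = th * th * (th - 1)
        return float(h00 * y0 + h10 * h * f0 + h01 * y1 + h11 * h * f1)

    def __call__(self, s, i: int = 0):
        if np.isscalar(s):
            return self.component(float(s), i)
        return np.array([self.component(float(v), i) for v in np.asarray(s)])

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.ts}
        for i in range(self.ys.shape[1]):
            cols[f"x{i}"] = self.ys[:, i]
        return pd.DataFrame(cols)


def integrate(
    system: FirstOrderDelaySystem, t_end: float, step: float
) -> DenseSolution:
    """Integrate a companion delay system by RK4 with dense delayed lookups.

    The uniform grid is augmented with every constant-lag multiple below
    ``t_end`` (derivative discontinuities propagate along those), and the
    history function serves every delayed argument at or below alpha.
    Constant lags should not be smaller than the step; within the leading
    transient of proportional lags the current step is bridged by first-order
    extrapolation.
    """
    import bisect

    if step <= 0:
        raise ValueError("step must be positive")
    alpha = system.alpha
    d = system.dimension

    events = {alpha, t_end}
    for order, arg in system.delayed_terms:
        coeffs = arg.poly_coeffs
        if len(coeffs) == 2 and abs(coeffs[1] - 1.0) < 1e-14 and coeffs[0] < 0:
            tau = -coeffs[0]
            k = 1
            while alpha + k * tau < t_end - 1e-12:
                events.add(alpha + k * tau)
                k += 1
    events = sorted(events)

    ts: list[float] = [alpha]
    ys: list[np.ndarray] = [np.asarray(system.initial_state, dtype=float).copy()]
    fs: list[np.ndarray] = []

    def hermite(s, order):
        k = bisect.bisect_right(ts, s) - 1
        k = min(max(k, 0), len(fs) - 2)  # only nodes with stored f are usable
        t0, t1 = ts[k], ts[k + 1]
        h = t1 - t0
        th = (s - t0) / h
        y0, y1 = ys[k][order], ys[k + 1][order]
        f0, f1 = fs[k][order], fs[k + 1][order]
        h00 = (1 + 2 * th) * (1 - th) ** 2
        h10 = th * (1 - th) ** 2
        h01 = th * th * (3 - 2 * th)
        h11 = th * th * (th - 1)
        return h00 * y0 + h10 * h * f0 + h01 * y1 + h11 * h * f1

    def lookup(order, s):
        if s <= alpha + 1e-14:
            return system.history_derivative(order, s)
        if len(fs) >= 2 and s <= ts[len(fs) - 1] + 1e-14:
            return hermite(s, order)
        # bridge the current step (early pantograph transient, first step)
        j = len(fs) - 1
        return float(ys[j][order] + (s - ts[j]) * fs[j][order])

    def f(t, y):
        u = [lookup(order, float(arg(t))) for order, arg in system.delayed_terms]
        dy = np.empty(d)
        dy[:-1] = y[1:]
        dy[-1] = system.rhs(t, y, u)
        if not np.all(np.isfinite(dy)):
            raise RuntimeError(f"non-finite state derivative at t={t}")
        return dy

    fs.append(f(alpha, ys[0]))

    for e0, e1 in zip(events[:-1], events[1:]):
        nsub = max(1, int(np.ceil((e1 - e0) / step - 1e-12)))
        h = (e1 - e0) / nsub
        for j in range(nsub):
            t = e0 + j * h
            y = ys[-1]
            k1 = fs[-1]
            k2 = f(t + h / 2, y + h / 2 * k1)
            k3 = f(t + h / 2, y + h / 2 * k2)
            k4 = f(t + h, y + h * k3)
            y1 = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            ts.append(t + h)
            ys.append(y1)
            fs.append(f(t + h, y1))

    return DenseSolution(ts=np.array(ts), ys=np.array(ys), fs=np.array(fs))


def manufactured_problem(
    seed: int,
    order: int = 1,
    degree: int = 3,
    delay_spec=None,
    nonlinear: bool = False,
    interval: tuple[float, float] = (0.0, 1.0),
):
    """Random delay problem with a known polynomial exact solution.

    A degree-``degree`` polynomial with coefficients uniform on [-2, 2] is
    declared the exact solution; the structural part combines the undelayed
    highest derivative with delayed lower-order terms (constant and
    proportional lags drawn from ``delay_spec`` or a default pool), plus an
    optional squared term when ``nonlinear``; the forcing is derived
    symbolically. Returns (problem, exact coefficient vector).
    """
    if degree < order:
        raise ValueError("exact-solution degree must be >= problem order")
    rng = np.random.default_rng(seed)
    coeffs = rng.uniform(-2.0, 2.0, size=degree + 1)
    while abs(coeffs[-1]) < 0.2:
        coeffs[-1] = rng.uniform(-2.0, 2.0)
    exact = sum(sp.Float(c, 17) * T**k for k, c in enumerate(coeffs))

    if delay_spec is None:
        delay_spec = [T - sp.Rational(1, 2), T / 2, T - sp.Rational(3, 10), T / 3]
    delays = [sp.sympify(h) for h in delay_spec]

    structural = x_func(order)(T)
    for _ in range(2):
        i = int(rng.integers(0, order))
        h = delays[int(rng.integers(0, len(delays)))]
        a = float(rng.uniform(-1.5, 1.5))
        structural += sp.Float(a, 17) * x_func(i)(h)
    if nonlinear:
        h = delays[int(rng.integers(0, len(delays)))]
        b = float(rng.uniform(0.3, 1.0))
        structural += sp.Float(b, 17) * x_func(0)(h) ** 2

    residual = derive_forcing(structural, exact, order, interval)

    alpha = interval[0]
    rows = tuple(
        tuple(1.0 if i == j else 0.0 for i in range(order)) for j in range(order)
    )
    values = tuple(
        float(sp.diff(exact, T, j).subs(T, alpha)) for j in range(order)
    )
    conditions = InitialConditionSet(point=alpha, coeff_matrix=rows, values=values)
    problem = DDEProblem(
        order=order,
        interval=interval,
        residual=residual,
        conditions=conditions,
        exact=exact,
        name=f"manufactured-{seed}",
    )
    return problem, coeffs
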