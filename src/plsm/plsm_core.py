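"""Polynomial least-squares solver for delay differential equations.

The method approximates the solution of an order-n delay problem on
[alpha, beta] by a single global polynomial

    x~(t) = sum_{k=0}^m c_k t^k,       m > n,

whose n leading coefficients c_0..c_{n-1} are eliminated through the
initial conditions, and whose remaining (free) coefficients minimize the
integrated squared residual

    J(c_n, ..., c_m) = int_alpha^beta R(t, c)^2 dt.

Delayed arguments h(t) falling outside [alpha, beta] are evaluated by the
same global polynomial (analytic continuation); no history function enters
the ansatz. When the residual is affine in the coefficients, J is a convex
quadratic and the minimizer is obtained in one weighted linear
least-squares solve (optionally in 50-digit arithmetic); otherwise a
multi-start trust-region least-squares refinement is used.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import mpmath as mp
import numpy as np
import scipy.linalg
import sympy as sp
from scipy.optimize import least_squares
from sympy.core.function import AppliedUndef

from .dde_problem import DDEProblem, DerivativeTerm, T, _func_order

__all__ = [
    "PolynomialCandidate",
    "ConstraintElimination",
    "ObjectiveSpec",
    "SolveResult",
    "SolverError",
    "poly_derivative",
    "eval_delayed",
    "residual_eval",
    "build_constraint_elimination",
    "objective_J",
    "objective_gradient",
    "objective_symbolic",
    "solve_linear",
    "minimize_objective",
    "degree_search",
    "default_nodes",
    "ResidualEvaluator",
]

#: diagnostic grid size for sup-norm residual checks
DIAGNOSTIC_GRID = 1001

#: stationarity tolerance: converged iff ||grad J|| < RTOL_GRAD * max(1, J)
RTOL_GRAD = 1e-8


class SolverError(RuntimeError):
    pass


def poly_derivative(coeffs, order: int) -> np.ndarray:
    """Coefficients (ascending powers) of the order-th derivative."""
    if order < 0:
        raise ValueError("negative derivative order")
    c = np.asarray(coeffs, dtype=float)
    d = np.polynomial.polynomial.polyder(c, m=order) if order else c
    if d.size == 0:
        d = np.zeros(1)
    return d


@dataclass(frozen=True)
class PolynomialCandidate:
    """Ansatz polynomial sum c_k t^k in the monomial basis."""

    degree: int
    coeffs: tuple[float, ...]

    def __post_init__(self):
        if len(self.coeffs) != self.degree + 1:
            raise ValueError("coefficient count does not match degree")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite coefficients")

    @classmethod
    def from_coeffs(cls, coeffs) -> "PolynomialCandidate":
        coeffs = tuple(float(c) for c in coeffs)
        return cls(degree=len(coeffs) - 1, coeffs=coeffs)

    def __call__(self, t):
        return np.polynomial.polynomial.polyval(t, np.asarray(self.coeffs))

    def derivative(self, order: int = 1) -> "PolynomialCandidate":
        return PolynomialCandidate.from_coeffs(poly_derivative(self.coeffs, order))

    def as_sympy(self) -> sp.Expr:
        return sum(sp.Float(c, 17) * T**k for k, c in enumerate(self.coeffs))


def eval_delayed(candidate: PolynomialCandidate, term: DerivativeTerm, t):
    """Value of the term's derivative of the candidate at h(t).

    The candidate is treated as a single global polynomial, so arguments
    h(t) outside the problem interval are simply evaluated (analytic
    continuation convention)."""
    d = poly_derivative(candidate.coeffs, term.derivative_order)
    return np.polynomial.polynomial.polyval(term.argument(t), d)


# --------------------------------------------------------------------------
# residual evaluation machinery


class ResidualEvaluator:
    """Compiled residual R(t; c_0..c_m) and its coefficient gradient.

    Substitutes the symbolic ansatz into every x^(i)(h(t)) term of a
    problem's residual and lambdifies the result once per (problem, degree).
    """

    def __init__(self, problem: DDEProblem, m: int):
        self.problem = problem
        self.m = m
        self.csyms = sp.symbols(f"c0:{m + 1}")
        self.expr = self._substituted(problem.residual)
        args = (T, *self.csyms)
        self._f = sp.lambdify(args, self.expr, modules="numpy")
        grads = [sp.diff(self.expr, c) for c in self.csyms]
        self._g = [sp.lambdify(args, g, modules="numpy") for g in grads]
        self._f_mp = None

    _cache: dict = {}

    @classmethod
    def for_problem(cls, problem: DDEProblem, m: int) -> "ResidualEvaluator":
        key = (id(problem), m)
        ev = cls._cache.get(key)
        if ev is None or ev.problem is not problem:
            ev = cls(problem, m)
            cls._cache[key] = ev
        return ev

    def _substituted(self, expr: sp.Expr) -> sp.Expr:
        def repl(f):
            order = _func_order(f.func)
            h = f.args[0]
            out = sp.Integer(0)
            for k in range(self.m + 1 - order):
                fac = sp.ff(k + order, order)  # (k+order)!/k!
                out += fac * self.csyms[k + order] * h**k
            return out

        return expr.replace(lambda e: isinstance(e, AppliedUndef), repl)

    def value(self, ts, coeffs) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        out = self._f(ts, *coeffs)
        return np.broadcast_to(np.asarray(out, dtype=float), ts.shape).copy()

    def coeff_gradient(self, ts, coeffs) -> np.ndarray:
        """Array (m+1, len(ts)) of dR/dc_k."""
        ts = np.asarray(ts, dtype=float)
        rows = []
        for g in self._g:
            v = np.asarray(g(ts, *coeffs), dtype=float)
            rows.append(np.broadcast_to(v, ts.shape))
        return np.array(rows)

    def value_mp(self, t, coeffs):
        if self._f_mp is None:
            self._f_mp = sp.lambdify((T, *self.csyms), self.expr, modules="mpmath")
        return self._f_mp(t, *coeffs)


def residual_eval(problem: DDEProblem, candidate: PolynomialCandidate, t):
    """Residual R(t, x~) of the candidate, scalar in, scalar out (or array)."""
    ev = ResidualEvaluator.for_problem(problem, candidate.degree)
    scalar = np.isscalar(t)
    vals = ev.value(np.atleast_1d(np.asarray(t, dtype=float)), candidate.coeffs)
    if not np.all(np.isfinite(vals)):
        raise SolverError("residual evaluated to a non-finite value")
    return float(vals[0]) if scalar else vals


# --------------------------------------------------------------------------
# initial-condition elimination


@dataclass(frozen=True)
class ConstraintElimination:
    """Affine parametrization c = map_matrix @ free + map_offset of all
    coefficient vectors satisfying the initial conditions."""

    m: int
    order: int
    eliminated_indices: tuple[int, ...]
    map_matrix: np.ndarray  # (m+1, m-n+1)
    map_offset: np.ndarray  # (m+1,)

    @property
    def n_free(self) -> int:
        return self.map_matrix.shape[1]

    @property
    def free_indices(self) -> tuple[int, ...]:
        return tuple(k for k in range(self.m + 1) if k not in self.eliminated_indices)

    def full_coeffs(self, free) -> np.ndarray:
        return self.map_matrix @ np.asarray(free, dtype=float) + self.map_offset


def _constraint_matrix(problem: DDEProblem, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Linear system L c = s expressing the initial conditions on the
    monomial coefficients: L[j, k] = sum_i r_ij * k!/(k-i)! * alpha^(k-i)."""
    n = problem.order
    alpha = problem.conditions.point
    r = np.asarray(problem.conditions.coeff_matrix, dtype=float)
    s = np.asarray(problem.conditions.values, dtype=float)
    L = np.zeros((n, m + 1))
    for j in range(n):
        for i in range(n):
            if r[j, i] == 0.0:
                continue
            for k in range(i, m + 1):
                fac = 1.0
                for q in range(i):
                    fac *= k - q
                L[j, k] += r[j, i] * fac * alpha ** (k - i)
    return L, s


def build_constraint_elimination(problem: DDEProblem, m: int) -> ConstraintElimination:
    """Eliminate n coefficients through the initial conditions.

    The default eliminated set is {c_0, ..., c_{n-1}}; if that block of the
    constraint system is (near-)singular, the best-conditioned column subset
    found by QR with column pivoting is used instead.
    """
    n = problem.order
    # m = n is admissible (one free coefficient); m < n leaves none
    if m < n:
        raise SolverError(f"ansatz degree m={m} leaves no free coefficient (n={n})")
    L, s = _constraint_matrix(problem, m)

    eliminated = tuple(range(n))
    LE = L[:, list(eliminated)]
    if np.linalg.cond(LE) > 1e12:
        _, _, piv = scipy.linalg.qr(L, pivoting=True)
        eliminated = tuple(sorted(int(p) for p in piv[:n]))
        LE = L[:, list(eliminated)]
        if np.linalg.cond(LE) > 1e12:
            raise SolverError("initial-condition system is singular")

    free = [k for k in range(m + 1) if k not in eliminated]
    LF = L[:, free]
    sol_off = np.linalg.solve(LE, s)
    sol_map = -np.linalg.solve(LE, LF)

    M = np.zeros((m + 1, len(free)))
    off = np.zeros(m + 1)
    for col, k in enumerate(free):
        M[k, col] = 1.0
    for row, k in enumerate(eliminated):
        off[k] = sol_off[row]
        M[k, :] = sol_map[row, :]
    return ConstraintElimination(
        m=m, order=n, eliminated_indices=eliminated, map_matrix=M, map_offset=off
    )


def constraint_violation(problem: DDEProblem, candidate: PolynomialCandidate) -> float:
    """max_j |sum_i r_ij x~^(i)(alpha) - s_j|."""
    L, s = _constraint_matrix(problem, candidate.degree)
    return float(np.max(np.abs(L @ np.asarray(candidate.coeffs) - s)))


# --------------------------------------------------------------------------
# objective functional


def default_nodes(m: int) -> int:
    """Gauss-Legendre node count: enough for the squared residual of a
    degree-m ansatz composed with low-degree delay arguments."""
    return max(4 * m + 20, 200)


@dataclass(frozen=True)
class ObjectiveSpec:
    """How the functional J = int R^2 dt is evaluated."""

    mode: str = "gauss-quadrature"  # or "symbolic-exact"
    node_count: int | None = None  # None -> default_nodes(m)
    precision: str = "double"  # or "mp50" (50 significant digits)

    def __post_init__(self):
        if self.mode not in ("gauss-quadrature", "symbolic-exact"):
            raise ValueError(f"unknown objective mode {self.mode!r}")
        if self.node_count is not None and self.node_count < 2:
            raise ValueError("node_count must be >= 2")
        if self.precision not in ("double", "mp50"):
            raise ValueError(f"unknown precision {self.precision!r}")

    def nodes_for(self, m: int) -> int:
        return self.node_count if self.node_count is not None else default_nodes(m)


@functools.lru_cache(maxsize=64)
def _gauss_nodes(npts: int, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(npts)
    ts = 0.5 * (b - a) * x + 0.5 * (b + a)
    ws = 0.5 * (b - a) * w
    return ts, ws


@functools.lru_cache(maxsize=8)
def _gauss_nodes_mp(npts: int, a: float, b: float, dps: int = 50):
    """Gauss-Legendre nodes refined to dps digits by Newton iteration on the
    Legendre recurrence, starting from the double-precision nodes."""
    with mp.workdps(dps + 10):
        xs, _ = np.polynomial.legendre.leggauss(npts)
        nodes, weights = [], []
        half = (mp.mpf(b) - mp.mpf(a)) / 2
        mid = (mp.mpf(b) + mp.mpf(a)) / 2
        for x0 in xs:
            x = mp.mpf(float(x0))
            for _ in range(6):
                p0, p1 = mp.mpf(1), x
                for k in range(2, npts + 1):
                    p0, p1 = p1, ((2 * k - 1) * x * p1 - (k - 1) * p0) / k
                dp = npts * (x * p1 - p0) / (x * x - 1)
                x -= p1 / dp
            p0, p1 = mp.mpf(1), x
            for k in range(2, npts + 1):
                p0, p1 = p1, ((2 * k - 1) * x * p1 - (k - 1) * p0) / k
            dp = npts * (x * p1 - p0) / (x * x - 1)
            w = 2 / ((1 - x * x) * dp * dp)
            nodes.append(mid + half * x)
            weights.append(half * w)
    return tuple(nodes), tuple(weights)


def objective_J(
    problem: DDEProblem,
    elim: ConstraintElimination,
    free_coeffs,
    spec: ObjectiveSpec | None = None,
) -> float:
    """The functional J = int_alpha^beta R(t, c)^2 dt at the given free
    coefficients (full coefficients via the elimination map)."""
    spec = spec or ObjectiveSpec()
    free_coeffs = np.asarray(free_coeffs, dtype=float)
    if free_coeffs.size != elim.n_free:
        raise ValueError(
            f"expected {elim.n_free} free coefficients, got {free_coeffs.size}"
        )
    c = elim.full_coeffs(free_coeffs)
    a, b = problem.interval
    ev = ResidualEvaluator.for_problem(problem, elim.m)
    if spec.mode == "symbolic-exact":
        expr = ev.expr.subs({cs: sp.Float(v, 17) for cs, v in zip(ev.csyms, c)})
        val = sp.integrate(sp.expand(expr**2), (T, a, b))
        return float(val)
    ts, ws = _gauss_nodes(spec.nodes_for(elim.m), a, b)
    r = ev.value(ts, c)
    if not np.all(np.isfinite(r)):
        raise SolverError("non-finite residual at a quadrature node")
    return float(np.dot(ws, r * r))


def objective_gradient(
    problem: DDEProblem,
    elim: ConstraintElimination,
    free_coeffs,
    spec: ObjectiveSpec | None = None,
) -> np.ndarray:
    """Gradient of J with respect to the free coefficients."""
    spec = spec or ObjectiveSpec()
    free_coeffs = np.asarray(free_coeffs, dtype=float)
    c = elim.full_coeffs(free_coeffs)
    a, b = problem.interval
    ev = ResidualEvaluator.for_problem(problem, elim.m)
    ts, ws = _gauss_nodes(spec.nodes_for(elim.m), a, b)
    r = ev.value(ts, c)
    G = ev.coeff_gradient(ts, c)  # (m+1, nodes)
    dR_dfree = elim.map_matrix.T @ G  # (n_free, nodes)
    return 2.0 * dR_dfree @ (ws * r)


def objective_symbolic(problem: DDEProblem, m: int) -> tuple[sp.Expr, tuple[sp.Symbol, ...]]:
    """Closed-form J as a sympy expression in the free coefficient symbols
    (exact integration; requires the residual to be polynomial in t).

    Serves as an independent cross-check of the quadrature objective."""
    elim = build_constraint_elimination(problem, m)
    ev = ResidualEvaluator.for_problem(problem, m)
    free_syms = tuple(ev.csyms[k] for k in elim.free_indices)
    subs = {}
    for row, k in enumerate(elim.eliminated_indices):
        val = sp.nsimplify(elim.map_offset[k], rational=True, tolerance=1e-12)
        for col, kf in enumerate(elim.free_indices):
            coef = elim.map_matrix[k, col]
            if coef != 0.0:
                val += sp.nsimplify(coef, rational=True, tolerance=1e-12) * ev.csyms[kf]
        subs[ev.csyms[k]] = val
    expr = ev.expr.subs(subs, simultaneous=True)
    a, b = problem.interval
    J = sp.integrate(sp.expand(expr**2), (T, sp.nsimplify(a), sp.nsimplify(b)))
    return sp.expand(J), free_syms


# --------------------------------------------------------------------------
# solvers


@dataclass(frozen=True)
class SolveResult:
    """Minimizing polynomial T_m and its diagnostics."""

    polynomial: PolynomialCandidate
    objective_value: float
    gradient_norm: float
    max_residual: float
    status: str  # converged | max-iterations | singular
    free_coefficients: tuple[float, ...] = ()
    elimination: ConstraintElimination | None = field(default=None, repr=False)


def _finalize(problem, elim, free, spec, status=None) -> SolveResult:
    c = elim.full_coeffs(free)
    cand = PolynomialCandidate.from_coeffs(c)
    J = objective_J(problem, elim, free, spec)
    g = objective_gradient(problem, elim, free, spec)
    gnorm = float(np.linalg.norm(g))
    a, b = problem.interval
    grid = np.linspace(a, b, DIAGNOSTIC_GRID)
    ev = ResidualEvaluator.for_problem(problem, elim.m)
    maxR = float(np.max(np.abs(ev.value(grid, c))))
    if status is None:
        status = "converged" if gnorm < RTOL_GRAD * max(1.0, J) else "max-iterations"
    return SolveResult(
        polynomial=cand,
        objective_value=J,
        gradient_norm=gnorm,
        max_residual=maxR,
        status=status,
        free_coefficients=tuple(float(f) for f in free),
        elimination=elim,
    )


def _affine_design(problem, elim, spec):
    """Weighted design of an affine residual: R(t; f) = A(t) f + b(t)."""
    a, b = problem.interval
    ts, ws = _gauss_nodes(spec.nodes_for(elim.m), a, b)
    ev = ResidualEvaluator.for_problem(problem, elim.m)
    b0 = ev.value(ts, elim.full_coeffs(np.zeros(elim.n_free)))
    cols = []
    for k in range(elim.n_free):
        e = np.zeros(elim.n_free)
        e[k] = 1.0
        cols.append(ev.value(ts, elim.full_coeffs(e)) - b0)
    A = np.column_stack(cols)
    return ts, ws, A, b0


def solve_linear(
    problem: DDEProblem, m: int, spec: ObjectiveSpec | None = None
) -> SolveResult:
    """Global minimizer of the quadratic J for residuals affine in the
    coefficients, by weighted linear least squares.

    With ``spec.precision == 'mp50'`` the normal equations are assembled and
    solved in 50-digit arithmetic (high-degree monomial systems are very
    ill-conditioned in double precision)."""
    spec = spec or ObjectiveSpec()
    elim = build_constraint_elimination(problem, m)
    if spec.precision == "mp50":
        free = _solve_linear_mp(problem, elim, spec)
    else:
        ts, ws, A, b0 = _affine_design(problem, elim, spec)
        sw = np.sqrt(ws)
        Aw = A * sw[:, None]
        scale = np.linalg.norm(Aw, axis=0)
        scale[scale == 0.0] = 1.0
        sol, _, rank, _ = np.linalg.lstsq(Aw / scale, -b0 * sw, rcond=None)
        if rank < elim.n_free:
            raise SolverError("normal equations numerically singular")
        free = sol / scale
    return _finalize(problem, elim, free, spec)


def _solve_linear_mp(problem, elim, spec, dps: int = 50):
    a, b = problem.interval
    ev = ResidualEvaluator.for_problem(problem, elim.m)
    nodes, weights = _gauss_nodes_mp(spec.nodes_for(elim.m), a, b, dps)
    with mp.workdps(dps):
        nf = elim.n_free
        M = [[mp.mpf(float(elim.map_matrix[i, j])) for j in range(nf)] for i in range(elim.m + 1)]
        off = [mp.mpf(float(v)) for v in elim.map_offset]
        rows_b = []
        rows_A = []
        for t in nodes:
            c0 = off
            rb = ev.value_mp(t, c0)
            rows_b.append(rb)
            row = []
            for k in range(nf):
                ck = [off[i] + M[i][k] for i in range(elim.m + 1)]
                row.append(ev.value_mp(t, ck) - rb)
            rows_A.append(row)
        G = mp.zeros(nf, nf)
        rhs = mp.zeros(nf, 1)
        for w, row, rb in zip(weights, rows_A, rows_b):
            for i in range(nf):
                rhs[i] -= w * row[i] * rb
                for j in range(i, nf):
                    G[i, j] += w * row[i] * row[j]
        for i in range(nf):
            for j in range(i):
                G[i, j] = G[j, i]
        try:
            sol = mp.lu_solve(G, rhs)
        except ZeroDivisionError as err:
            raise SolverError("normal equations singular in extended precision") from err
        return np.array([float(v) for v in sol])


def minimize_objective(
    problem: DDEProblem,
    m: int,
    spec: ObjectiveSpec | None = None,
    starts: int = 8,
    seed: int = 0,
    extra_starts=(),
) -> SolveResult:
    """Minimize J over the free coefficients.

    Residuals affine in the coefficients are dispatched to
    :func:`solve_linear`. Otherwise a trust-region reflective least-squares
    refinement (analytic Jacobian) is run from ``starts`` initial points:
    the zero free vector first, the rest standard normal draws from ``seed``;
    ``extra_starts`` (e.g. a warm start from a lower degree) are appended.
    Ties are broken by lowest J, then lowest gradient norm.
    """
    from .dde_problem import _probe_affine

    spec = spec or ObjectiveSpec()
    if _probe_affine(problem, seed=0):
        return solve_linear(problem, m, spec)

    elim = build_constraint_elimination(problem, m)
    a, b = problem.interval
    ts, ws = _gauss_nodes(spec.nodes_for(m), a, b)
    sw = np.sqrt(ws)
    ev = ResidualEvaluator.for_problem(problem, m)

    def resid(f):
        r = ev.value(ts, elim.full_coeffs(f))
        r[~np.isfinite(r)] = 1e100
        return sw * r

    def jac(f):
        G = ev.coeff_gradient(ts, elim.full_coeffs(f))
        J = (elim.map_matrix.T @ G).T  # (nodes, n_free)
        J[~np.isfinite(J)] = 0.0
        return sw[:, None] * J

    rng = np.random.default_rng(seed)
    inits = [np.zeros(elim.n_free)]
    for _ in range(max(0, starts - 1)):
        inits.append(rng.standard_normal(elim.n_free))
    inits.extend(np.asarray(x, dtype=float) for x in extra_starts)

    best = None
    for f0 in inits:
        try:
            res = least_squares(
                resid, f0, jac=jac, method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=400,
            )
        except Exception:
            continue
        cand = _finalize(problem, elim, res.x, spec)
        key = (cand.objective_value, cand.gradient_norm)
        if best is None or key < (best.objective_value, best.gradient_norm):
            best = cand
    if best is None:
        raise SolverError("no optimization start converged")
    return best


def degree_search(
    problem: DDEProblem,
    epsilon: float,
    m_min: int,
    m_max: int,
    spec: ObjectiveSpec | None = None,
    seed: int = 0,
    starts: int = 8,
):
    """Sweep ansatz degrees m_min..m_max and stop at the first degree whose
    sup-norm residual on the diagnostic grid drops below ``epsilon``.

    Each degree is warm-started from the previous minimizer (zero-padded), so
    the recorded J values are non-increasing in m. Returns the accepted (or
    best-found) :class:`SolveResult` and the trace of (m, J, max|R|).
    """
    n = problem.order
    if not (n <= m_min <= m_max):
        raise SolverError("need n <= m_min <= m_max")
    trace = []
    best = None
    warm = None
    for m in range(m_min, m_max + 1):
        extra = []
        if warm is not None:
            elim = build_constraint_elimination(problem, m)
            free_idx = elim.free_indices
            prev = dict(zip(warm[0], warm[1]))
            extra.append(np.array([prev.get(k, 0.0) for k in free_idx]))
        result = minimize_objective(
            problem, m, spec=spec, starts=starts, seed=seed, extra_starts=extra
        )
        if best is not None and result.objective_value > best.objective_value + 1e-12:
            result = best  # keep the lower-J solution (monotone trace)
        trace.append((m, result.objective_value, result.max_residual))
        if best is None or result.objective_value <= best.objective_value:
            best = result
        warm = (
            result.elimination.free_indices if result.elimination is not None else (),
            result.free_coefficients,
        )
        if result.max_residual < epsilon:
            return result, trace
    return best, trace
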