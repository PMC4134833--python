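"""Solution-quality checks and error tables.

Two notions of approximation quality are used: an eps-approximate
polynomial solution satisfies the sup-norm bound |R(t, x~)| < eps on the
whole interval, while a weak delta-approximate solution satisfies the
integral bound int R^2 dt <= delta. Every eps-approximate solution is a
weak eps^2*(beta - alpha)-approximate solution, which the property tests
exercise as an inequality on every computed result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import sympy as sp

from .dde_problem import DDEProblem, T
from .plsm_core import (
    ConstraintElimination,
    ObjectiveSpec,
    PolynomialCandidate,
    ResidualEvaluator,
    SolveResult,
    build_constraint_elimination,
    objective_J,
)

__all__ = [
    "ToleranceSpec",
    "ErrorTable",
    "max_abs_residual",
    "weak_norm",
    "is_eps_solution",
    "is_weak_solution",
    "error_table",
    "write_report",
    "read_report",
]


@dataclass(frozen=True)
class ToleranceSpec:
    epsilon: float  # sup-norm residual bound
    delta: float  # integrated squared-residual bound

    def __post_init__(self):
        if self.epsilon <= 0 or self.delta <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class ErrorTable:
    """Per-point absolute errors |x~(t) - reference(t)|."""

    data: pd.DataFrame  # columns: t, abs_error
    reference_kind: str  # "exact" | "numerical"

    def __post_init__(self):
        if list(self.data.columns) != ["t", "abs_error"]:
            raise ValueError("error table must have columns (t, abs_error)")
        if (self.data["abs_error"] < 0).any():
            raise ValueError("negative absolute error")

    def at(self, t: float) -> float:
        idx = (self.data["t"] - t).abs().idxmin()
        row = self.data.loc[idx]
        if abs(row["t"] - t) > 1e-9:
            raise KeyError(f"no tabulation point at t={t}")
        return float(row["abs_error"])


def max_abs_residual(
    problem: DDEProblem, candidate: PolynomialCandidate, grid_points: int = 1001
) -> float:
    """Sup-norm of the residual over a uniform grid on [alpha, beta]."""
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    a, b = problem.interval
    grid = np.linspace(a, b, grid_points)
    ev = ResidualEvaluator.for_problem(problem, candidate.degree)
    vals = ev.value(grid, candidate.coeffs)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite residual on diagnostic grid")
    return float(np.max(np.abs(vals)))


def weak_norm(
    problem: DDEProblem,
    candidate: PolynomialCandidate,
    spec: ObjectiveSpec | None = None,
) -> float:
    """The integral int_alpha^beta R(t, x~)^2 dt."""
    elim = _identity_elimination(candidate.degree)
    return objective_J(problem, elim, np.asarray(candidate.coeffs), spec)


def _identity_elimination(m: int) -> ConstraintElimination:
    # all coefficients treated as free: weak_norm evaluates arbitrary candidates
    return ConstraintElimination(
        m=m,
        order=0,
        eliminated_indices=(),
        map_matrix=np.eye(m + 1),
        map_offset=np.zeros(m + 1),
    )


def is_eps_solution(problem, candidate, tol: ToleranceSpec, grid_points: int = 1001) -> bool:
    return max_abs_residual(problem, candidate, grid_points) < tol.epsilon


def is_weak_solution(problem, candidate, tol: ToleranceSpec) -> bool:
    return weak_norm(problem, candidate) <= tol.delta


def error_table(
    problem: DDEProblem,
    candidate: PolynomialCandidate,
    reference: sp.Expr | Callable[[float], float] | None = None,
    points: Sequence[float] | None = None,
    reference_kind: str | None = None,
) -> ErrorTable:
    """Absolute error of the candidate against a reference solution.

    ``reference`` may be a sympy expression of t, any callable, or None to
    use the problem's attached exact solution.
    """
    if reference is None:
        if problem.exact is None:
            raise ValueError("problem has no exact solution; pass a reference")
        reference = problem.exact
    if isinstance(reference, sp.Expr):
        fn = sp.lambdify(T, reference, modules="numpy")
        kind = reference_kind or "exact"
    else:
        fn = reference
        kind = reference_kind or "numerical"
    if points is None:
        points = np.linspace(*problem.interval, 11)
    rows = []
    for t in points:
        ref = float(fn(float(t)))
        if not np.isfinite(ref):
            raise ValueError(f"reference undefined at t={t}")
        rows.append((float(t), abs(float(candidate(t)) - ref)))
    df = pd.DataFrame(rows, columns=["t", "abs_error"])
    return ErrorTable(data=df, reference_kind=kind)


def write_report(
    result: SolveResult,
    table: ErrorTable | None,
    path: str | Path,
    problem_name: str = "",
) -> list[Path]:
    """Write a JSON report (coefficients and diagnostics) and, when an error
    table is present, a flat CSV beside it. Returns the written paths."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report = {
        "problem": problem_name,
        "degree": result.polynomial.degree,
        "coefficients": list(result.polynomial.coeffs),
        "objective_value": result.objective_value,
        "gradient_norm": result.gradient_norm,
        "max_residual": result.max_residual,
        "status": result.status,
    }
    written = []
    if table is not None:
        report["reference_kind"] = table.reference_kind
        report["error_table"] = {
            "t": table.data["t"].tolist(),
            "abs_error": table.data["abs_error"].tolist(),
        }
        csv_path = path.with_suffix(".csv")
        table.data.to_csv(csv_path, index=False)
        written.append(csv_path)
    path.write_text(json.dumps(report, indent=2))
    written.insert(0, path)
    return written


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
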