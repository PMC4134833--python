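"""The six packaged benchmark problems and their published reference data.

Each benchmark bundles a problem definition (shipped as a TOML fixture), the
ansatz degree of the published polynomial solution, the tabulation grid of
the published error tables, and the published per-point absolute errors of
this and competing methods (kept as reference constants for comparison
output only — they are never used by the solver).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .dde_problem import DDEProblem, parse_problem
from .diagnostics import ErrorTable, error_table, max_abs_residual
from .plsm_core import ObjectiveSpec, SolveResult, minimize_objective
from .reference_oracle import integrate, to_first_order

__all__ = [
    "BenchmarkSpec",
    "BenchmarkRun",
    "BENCHMARKS",
    "load_problem",
    "run_benchmark",
]

#: published absolute errors of the polynomial least-squares solutions
REFERENCE_ERRORS = {
    "app3": {0.2: 1.02e-8, 0.4: 6.14e-8, 0.6: 8.92e-8, 0.8: 1.02e-7, 1.0: 1.53e-7},
    "app4": {
        0.0: 0.0, 0.2: 6.255e-13, 0.4: 7.193e-12, 0.6: 1.839e-11,
        0.8: 3.341e-11, 1.0: 5.642e-11,
    },
    "app5": {
        0.0: 0.0, 0.05: 6.33e-2, 0.1: 7.86e-2, 0.15: 7.13e-2, 0.2: 5.83e-2,
        0.25: 4.47e-2, 0.3: 3.27e-2, 0.35: 2.32e-2, 0.4: 1.66e-2,
        0.5: 1.07e-2, 1.0: 7.41e-4, 1.5: 6.14e-4,
    },
}

#: published errors of competing methods (reference constants only)
COMPETING_ERRORS = {
    "app3": {
        "VIM": {0.2: 5e-5, 0.4: 1e-4, 0.6: 5e-5, 0.8: 1e-4, 1.0: 5e-4},
        "HPM": {0.2: 1.34e-5, 0.4: 5.13e-5, 0.6: 6.26e-6, 0.8: 2.21e-5, 1.0: 3.69e-5},
    },
    "app4": {
        "TM": {0.2: 8.54e-8, 0.4: 5.36e-6, 0.6: 5.95e-5, 0.8: 3.26e-4, 1.0: 1.21e-3},
        "CM": {0.2: 3.70e-7, 0.4: 2.38e-6, 0.6: 5.97e-6, 0.8: 3.48e-5, 1.0: 2.03e-4},
        "HCM": {0.2: 6.200e-9, 0.4: 5.760e-8, 0.6: 1.796e-7, 0.8: 3.735e-7, 1.0: 6.368e-7},
        "JRC": {0.2: 3.605e-8, 0.4: 9.299e-9, 0.6: 3.503e-10, 0.8: 8.345e-9, 1.0: 1.161e-8},
    },
    "app5": {
        "ADM": {0.05: 1.04e-1, 0.1: 1.38e-1, 0.15: 1.31e-1, 0.2: 1.26e-1,
                0.25: 1.25e-1, 0.3: 1.26e-1, 0.35: 1.27e-1, 0.4: 1.29e-1},
        "VIM": {0.5: 1.59e-2, 1.0: 4.3e-3, 1.5: 8.2e-4},
    },
}

#: published minimizing polynomials, ascending monomial coefficients
REFERENCE_COEFFS = {
    "app1": (-2.0, -1.0, 1.0),
    "app2": (0.0, 0.0, 1.0),
    "app3": (1 / 3, 1 / 6, -0.0416659, -0.00309479, 0.00088928, -3.8337691e-6),
    "app4": (1.0, -1.0, 0.5, -0.166667, 0.0416666, -0.00833288,
             0.00138757, -0.000196271, 0.0000227752, -1.6853299e-6),
    "app5": (1.0, -3.89839, 16.3752, -38.6665, 52.059, -39.5946, 15.8186, -2.57841),
    "app6": (0.1, -0.00895158, 0.000388792, 0.000175863, -0.0000361911, -7.0502e-6),
}


@dataclass(frozen=True)
class BenchmarkSpec:
    identifier: str
    title: str
    degree: int
    tabulation_points: tuple[float, ...]
    reference_kind: str  # exact | numerical | residual-only
    precision: str = "double"
    starts: int = 8
    oracle_history: float | None = None  # constant history for the oracle
    oracle_step: float = 1e-4


BENCHMARKS: dict[str, BenchmarkSpec] = {
    "app1": BenchmarkSpec(
        "app1", "nonlinear Riccati-type equation with shifted arguments", 2,
        (0.0, 0.2, 0.4, 0.6, 0.8, 1.0), "exact",
    ),
    "app2": BenchmarkSpec(
        "app2", "neutral second-order equation with proportional delays", 2,
        (0.0, 0.2, 0.4, 0.6, 0.8, 1.0), "exact",
    ),
    "app3": BenchmarkSpec(
        "app3", "pantograph-type nonlinear equation", 5,
        (0.2, 0.4, 0.6, 0.8, 1.0), "exact",
    ),
    "app4": BenchmarkSpec(
        "app4", "generalized pantograph equation (third order)", 9,
        (0.0, 0.2, 0.4, 0.6, 0.8, 1.0), "exact", precision="mp50",
    ),
    "app5": BenchmarkSpec(
        "app5", "delayed logistic population model", 7,
        (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.5, 1.0, 1.5),
        "numerical", oracle_history=1.0,
    ),
    "app6": BenchmarkSpec(
        "app6", "scalar equation with two constant delays", 5,
        (), "residual-only",
    ),
}


def load_problem(identifier: str) -> DDEProblem:
    """Parse a packaged benchmark problem definition."""
    if identifier not in BENCHMARKS:
        raise KeyError(f"unknown benchmark {identifier!r}")
    text = (
        importlib.resources.files("plsm.problems")
        .joinpath(f"{identifier}.toml")
        .read_text()
    )
    return parse_problem(text)


@dataclass(frozen=True)
class BenchmarkRun:
    spec: BenchmarkSpec
    problem: DDEProblem
    result: SolveResult
    table: ErrorTable | None
    reference_errors: dict[float, float] | None

    def comparison(self):
        """DataFrame of computed vs published absolute errors, with ratios."""
        import pandas as pd

        if self.table is None:
            return None
        rows = []
        for _, row in self.table.data.iterrows():
            t, err = row["t"], row["abs_error"]
            pub = None
            if self.reference_errors:
                for tp, v in self.reference_errors.items():
                    if abs(tp - t) < 1e-9:
                        pub = v
                        break
            ratio = err / pub if pub else np.nan
            rows.append((t, err, pub, ratio))
        return pd.DataFrame(rows, columns=["t", "abs_error", "published", "ratio"])


def run_benchmark(
    identifier: str,
    degree: int | None = None,
    seed: int = 0,
    starts: int | None = None,
    precision: str | None = None,
    oracle_step: float | None = None,
) -> BenchmarkRun:
    """Solve one packaged benchmark with its published settings.

    The error table is computed against the problem's exact solution when
    one exists, against the method-of-steps reference (constant history)
    for the delayed logistic model, and omitted for the residual-only
    benchmark.
    """
    spec = BENCHMARKS[identifier]
    problem = load_problem(identifier)
    m = degree if degree is not None else spec.degree
    obj = ObjectiveSpec(precision=precision or spec.precision)
    result = minimize_objective(
        problem, m, spec=obj, starts=starts if starts is not None else spec.starts,
        seed=seed,
    )

    table = None
    if spec.reference_kind == "exact":
        table = error_table(
            problem, result.polynomial, points=spec.tabulation_points
        )
    elif spec.reference_kind == "numerical":
        system = to_first_order(problem, history=spec.oracle_history)
        dense = integrate(
            system, problem.interval[1], oracle_step or spec.oracle_step
        )
        table = error_table(
            problem,
            result.polynomial,
            reference=lambda t: dense(t),
            points=spec.tabulation_points,
            reference_kind="numerical",
        )
    return BenchmarkRun(
        spec=spec,
        problem=problem,
        result=result,
        table=table,
        reference_errors=REFERENCE_ERRORS.get(identifier),
    )
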