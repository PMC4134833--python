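# plsm — polynomial least-squares solutions of delay differential equations

Delay differential equations (DDEs) — equations whose derivatives depend on
the solution at shifted times — are the workhorse models for phenomena with
memory: delayed density dependence in population biology, pantograph dynamics,
epidemic and neural-network models. Closed-form solutions exist only in
special cases, and classical integrators struggle with proportional delays
and neutral terms (the highest derivative itself delayed).

This package computes **analytical approximate polynomial solutions** for the
general initial-value problem

```
F(x⁽ⁿ⁾(hₙ(t)), x⁽ⁿ⁻¹⁾(hₙ₋₁(t)), …, x′(h₁(t)), x(h₀(t)), t) = 0,   t ∈ [α, β],

Σᵢ rᵢⱼ x⁽ⁱ⁾(α) = sⱼ,   j = 1…n,
```

where every delay argument `hₖ(t)` is a polynomial in `t` (constant lags
`t − τ`, proportional lags `q·t`, or any other polynomial — neutral and
advanced terms included). The ansatz is a single global polynomial
`x̃(t) = Σ cₖ tᵏ`; the initial conditions eliminate n coefficients and the
remaining ones minimize the integrated squared residual

```
J(cₙ, …, c_m) = ∫αβ R²(t, c₀, …, c_m) dt,       R(t, x̃) = F(x̃⁽ⁿ⁾(hₙ(t)), …, t).
```

For residuals affine in the coefficients, J is a convex quadratic and the
minimizer comes from one weighted linear least-squares solve (optionally in
50-digit arithmetic); nonlinear residuals are handled by multi-start
trust-region least squares with an analytic Jacobian. A candidate with
`max |R| < ε` on the interval is an ε-approximate solution; `∫R² ≤ δ` makes
it a weak δ-approximate solution, and `∫R² ≤ (max|R|)²·(β − α)` links the two.

The package also ships an independent **method-of-steps reference
integrator** (RK4 with cubic-Hermite dense output and an explicit history
function) and a **manufactured-problem generator** for validation, plus six
packaged benchmark problems, including the delayed logistic (Hutchinson)
population model `x′ = 2x(t)(1 − x(t−0.1)/0.5)`.

## Worked example

Problems are TOML files; `x{i}(arg)` denotes the i-th derivative evaluated at
a polynomial argument:

```toml
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
```

`plsm solve problem.toml --degree 2` recovers the exact solution `t²`
(coefficients `[0, 0, 1]`, J ≈ 2e-32). Running a packaged benchmark — the
nonlinear pantograph equation with exact solution `sin(t/3)/2 + cos(t/2)/3` —
prints the error table next to the published one:

```
$ plsm benchmark app3
app3: pantograph-type nonlinear equation
degree 5, J=1.422992e-12, max|R|=3.619709e-06, status=converged
  t    abs_error    published    ratio
0.2 1.013858e-08 1.020000e-08 0.993978
0.4 6.126195e-08 6.140000e-08 0.997752
0.6 8.917841e-08 8.920000e-08 0.999758
0.8 1.020598e-07 1.020000e-07 1.000586
1.0 1.535768e-07 1.530000e-07 1.003770
```

`abs_error` is |x̃(t) − x_exact(t)| for the computed degree-5 minimizer;
`ratio` compares it with the published value. From Python:

```python
from plsm import load_problem, minimize_objective

problem = load_problem("app5")          # delayed logistic model
result = minimize_objective(problem, 7)
result.polynomial(1.0)                  # population at t = 1
result.max_residual                     # sup-norm residual on [0, 1.5]
```

`plsm list` shows all six packaged benchmarks and their settings.

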