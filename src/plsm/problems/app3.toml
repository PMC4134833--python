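name = "app3"
# Pantograph-type nonlinear second-order equation; forcing derived from the
# exact solution sin(t/3)/2 + cos(t/2)/3 (manufactured form).
order = 2
interval = [0.0, 1.0]
residual = "x2(t) - exp(-t)*x1(t - 1/5) - (t - 1)*x0(t) + 2*x0(t/3) - x0(t)^2"
exact = "sin(t/3)/2 + cos(t/2)/3"
derive_forcing = true
[[conditions]]
coeffs = [3.0, 6.0]
value = 2.0
[[conditions]]
coeffs = [-2.0, 1.0]
value = -0.5
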