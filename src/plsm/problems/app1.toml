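name = "app1"
# First-order nonlinear (Riccati-type) equation with three shifted arguments;
# the forcing is derived from the exact solution t^2 - t - 2.
order = 1
interval = [0.0, 1.0]
residual = "x1(t - 2) - t^2*x0(2*t - 3) - x0(t - 1)^2"
exact = "t^2 - t - 2"
derive_forcing = true
[[conditions]]
coeffs = [1.0]
value = -2.0
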