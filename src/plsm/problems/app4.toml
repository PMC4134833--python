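name = "app4"
# Third-order generalized pantograph equation with constant lag 0.3;
# exact solution exp(-t).
order = 3
interval = [0.0, 1.0]
residual = "x3(t) + x0(t) + x0(t - 3/10) - exp(-t + 3/10)"
exact = "exp(-t)"
[[conditions]]
coeffs = [1.0, 0.0, 0.0]
value = 1.0
[[conditions]]
coeffs = [0.0, 1.0, 0.0]
value = -1.0
[[conditions]]
coeffs = [0.0, 0.0, 1.0]
value = 1.0
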