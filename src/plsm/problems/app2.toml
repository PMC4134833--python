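name = "app2"
# Second-order neutral equation with proportional delays t/2; exact solution t^2.
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
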