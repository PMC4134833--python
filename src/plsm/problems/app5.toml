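name = "app5"
# Delayed logistic (Hutchinson) population model x' = r x (1 - x(t - tau)/K)
# with growth rate r = 2, lag tau = 0.1, carrying capacity K = 0.5.
order = 1
interval = [0.0, 1.5]
residual = "x1(t) - 2*x0(t)*(1 - x0(t - 1/10)/0.5)"
[[conditions]]
coeffs = [1.0]
value = 1.0
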