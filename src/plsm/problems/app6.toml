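name = "app6"
# Scalar linear equation with two constant delays pi and 2*pi and periodic
# coefficients 0.2/pi. The equation is linear and homogeneous, so solutions
# scale with the initial value; the published polynomial corresponds to
# x(0) = 0.1, which is the normalization adopted here.
order = 1
interval = [0.0, 1.0]
residual = "x1(t) + (0.2/pi)*x0(t - pi)*sin(t)^2 + (0.2/pi)*x0(t - 2*pi)*cos(t)^2"
[[conditions]]
coeffs = [1.0]
value = 0.1
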