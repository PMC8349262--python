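"""Evaluate the conditional stress-strength reliability in closed form.

R^{|a,b} = P(X > Y | X > a, Y > b) for X ~ Ku(alpha, beta1), Y ~ Ku(alpha, beta2).
The quadrature route integrates the defining tail integrals and should agree
with the closed form to ~1e-10 — a useful self-check on any new parameter set.
"""

from kwstress import (
    ModelParams,
    Thresholds,
    conditional_reliability,
    conditional_reliability_numeric,
)

t = Thresholds(a=0.1, b=0.2)
for theta in (ModelParams(5.0, 3.5, 3.25), ModelParams(1.25, 7.0, 4.2)):
    closed = conditional_reliability(theta, t)
    numeric = conditional_reliability_numeric(theta, t)
    print(f"alpha={theta.alpha}, beta1={theta.beta1}, beta2={theta.beta2}:")
    print(f"  closed form : {closed:.9f}")
    print(f"  quadrature  : {numeric:.9f}  (independent check)")

# with equal thresholds the conditioning drops out entirely
eq = conditional_reliability(ModelParams(5.0, 3.5, 3.25), Thresholds(0.3, 0.3))
print(f"equal thresholds a=b=0.3 -> beta2/(beta1+beta2) = {eq:.6f}")
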