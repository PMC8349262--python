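"""Conditional stress-strength reliability R^{|a,b} = P(X > Y | X > a, Y > b).

For independent X ~ Ku(α, β₁) (strength) and Y ~ Ku(α, β₂) (stress) sharing
the first shape parameter, the conditional reliability has a three-case
closed form in the ordering of the thresholds a and b:

    a = b:  β₂ / (β₁ + β₂)
    a < b:  β₂/(β₁+β₂) · [(1 − b^α)/(1 − a^α)]^{β₁}
    a > b:  1 − β₁/(β₁+β₂) · [(1 − a^α)/(1 − b^α)]^{β₂}

With a = b the thresholds drop out entirely and the unconditional
P(X > Y) = β₂/(β₁+β₂) is recovered.  A quadrature evaluation of the defining
integrals is provided as an independent numerical route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .distribution import KwParams, kw_cdf, kw_pdf

__all__ = [
    "ModelParams",
    "Thresholds",
    "conditional_reliability",
    "conditional_reliability_numeric",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameter triple (α, β₁, β₂): common shape plus per-sample shapes."""

    alpha: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta1 > 0 and self.beta2 > 0):
            raise ValueError(
                "all shape parameters must be strictly positive, got "
                f"({self.alpha}, {self.beta1}, {self.beta2})"
            )

    @property
    def x_params(self) -> KwParams:
        return KwParams(self.alpha, self.beta1)

    @property
    def y_params(self) -> KwParams:
        return KwParams(self.alpha, self.beta2)


@dataclass(frozen=True)
class Thresholds:
    """Known conditioning constants (a, b), each in [0, 1).

    Values ≥ 1 are rejected: the conditioning events {X > a}, {Y > b} would
    have probability zero on the unit-interval support.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0 <= self.a < 1 and 0 <= self.b < 1):
            raise ValueError(f"thresholds must lie in [0, 1), got a={self.a}, b={self.b}")


def _log_one_minus_pow(t: float, alpha: float) -> float:
    """ln(1 − t^α), stable for small t^α."""
    if t == 0.0:
        return 0.0
    return float(np.log1p(-np.exp(alpha * np.log(t))))


def conditional_reliability(theta: ModelParams, t: Thresholds) -> float:
    """Closed-form R^{|a,b}; dispatches on the exact ordering of a and b."""
    b1, b2 = theta.beta1, theta.beta2
    if t.a == t.b:
        return b2 / (b1 + b2)
    la = _log_one_minus_pow(t.a, theta.alpha)
    lb = _log_one_minus_pow(t.b, theta.alpha)
    if t.a < t.b:
        return b2 / (b1 + b2) * float(np.exp(b1 * (lb - la)))
    return 1.0 - b1 / (b1 + b2) * float(np.exp(b2 * (la - lb)))


def conditional_reliability_numeric(
    theta: ModelParams, t: Thresholds, tol: float = 1e-10
) -> float:
    """R^{|a,b} via adaptive quadrature of the defining integrals.

    P(X > Y, X > a, Y > b) is written as a single integral over the upper
    tail (the integrands vanish beyond 1, so integration stops there) and
    divided by [1 − F_X(a)][1 − F_Y(b)].  Serves as an independent oracle
    for the closed form.
    """
    px, py = theta.x_params, theta.y_params
    denom = (1.0 - kw_cdf(t.a, px)) * (1.0 - kw_cdf(t.b, py))

    if t.a <= t.b:
        # X > Y > b (and Y > b ≥ a makes X > a automatic)
        lo = t.b

        def integrand(y: float) -> float:
            return (1.0 - kw_cdf(y, px)) * kw_pdf(y, py)

    else:
        # X > a with Y anywhere in (b, X)
        lo = t.a

        def integrand(x: float) -> float:
            return (kw_cdf(x, py) - kw_cdf(t.b, py)) * kw_pdf(x, px)

    num, err = integrate.quad(integrand, lo, 1.0, epsabs=tol, epsrel=tol, limit=200)
    if err > max(1e-8, 100 * tol):
        raise RuntimeError(f"quadrature did not reach requested tolerance (err={err})")
    return num / denom
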