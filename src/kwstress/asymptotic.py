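"""Fisher information, delta-method variance and Wald intervals for R̂^{|a,b}.

The observed information I(θ) is the negated Hessian of the log-likelihood.
Its expectation J(θ) has closed-form entries through beta, digamma and
trigamma functions, driven by the two moment integrals

    ∫₀¹ t^{x−1}(1−t)^{y−1} ln t dt   = B(x,y)[ψ(x) − ψ(x+y)],
    ∫₀¹ t^{x−1}(1−t)^{y−1} ln² t dt  = B(x,y)[(ψ(x) − ψ(x+y))² + ψ′(x) − ψ′(x+y)]

applied to t = x^α ~ Beta(1, β).  The closed forms need B(2, β−2) (the
α-curvature term) resp. B(2, β−1) (the mixed term), so they are valid only
for β > 2 resp. β > 1; below those the expectations still exist and are
evaluated by adaptive quadrature instead.

The asymptotic variance of the plug-in reliability estimate is the delta
method quadratic form ġ Σ ġᵀ with Σ = J(θ)⁻¹ and ġ the analytic gradient of
the closed-form reliability in (α, β₁, β₂).  A fully expanded scalar variance
(through the aggregates A, C, D and beta/digamma constants) is kept as a
cross-check layer; the quadratic form is authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special, stats

from .mle import TwoSampleData
from .reliability import ModelParams, Thresholds

__all__ = [
    "InfoMatrix",
    "DeltaComponents",
    "WaldInterval",
    "observed_information",
    "expected_information",
    "covariance",
    "delta_gradient",
    "r_variance",
    "wald_interval",
]

_PSI2 = float(special.digamma(2.0))
_PSI2P = float(special.polygamma(1, 2.0))  # trigamma(2) = pi^2/6 - 1


@dataclass(frozen=True)
class InfoMatrix:
    """3×3 information matrix indexed (α, β₁, β₂); kind ∈ {observed, expected}."""

    entries: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.shape != (3, 3):
            raise ValueError("information matrix must be 3x3")
        object.__setattr__(self, "entries", e)


@dataclass(frozen=True)
class WaldInterval:
    lower: float
    upper: float
    level: float
    se: float

    @property
    def length(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class DeltaComponents:
    """Delta-method variance of R̂ plus the pieces it is assembled from."""

    case: str                      # "a=b", "a<b" or "a>b"
    grad: np.ndarray               # analytic ġ = (∂R/∂α, ∂R/∂β₁, ∂R/∂β₂)
    sigma: np.ndarray              # Σ = J⁻¹
    sigma_sq: float                # canonical ġ Σ ġᵀ
    sigma_sq_expanded: float | None = None   # scalar closed-form route (β's > 2)
    constants: dict = field(default_factory=dict)


def observed_information(theta: ModelParams, d: TwoSampleData) -> InfoMatrix:
    """I(θ) = −Hessian of the log-likelihood at θ, evaluated analytically."""
    a, b1, b2 = theta.alpha, theta.beta1, theta.beta2
    log_x, log_y = np.log(d.x), np.log(d.y)
    tx, ty = np.exp(a * log_x), np.exp(a * log_y)

    i11 = (
        (d.n + d.m) / a**2
        + (b1 - 1.0) * float((tx * log_x**2 / (1.0 - tx) ** 2).sum())
        + (b2 - 1.0) * float((ty * log_y**2 / (1.0 - ty) ** 2).sum())
    )
    i12 = float((tx * log_x / (1.0 - tx)).sum())
    i13 = float((ty * log_y / (1.0 - ty)).sum())
    ent = np.array(
        [
            [i11, i12, i13],
            [i12, d.n / b1**2, 0.0],
            [i13, 0.0, d.m / b2**2],
        ]
    )
    return InfoMatrix(ent, "observed")


def _curvature_const(beta: float) -> float:
    """K(β) = (β−1)·E[t ln²t/(1−t)²·...] aggregate: β(β−1)∫ t(1−t)^{β−3} ln²t dt.

    Per-observation α-curvature beyond the 1/α² term is K(β)/α².
    """
    if beta > 2.0:
        return float(
            beta
            * (beta - 1.0)
            * special.beta(2.0, beta - 2.0)
            * ((_PSI2 - special.digamma(beta)) ** 2 + _PSI2P - special.polygamma(1, beta))
        )

    def f(t: float) -> float:
        return t * (1.0 - t) ** (beta - 3.0) * np.log(t) ** 2

    val, _ = integrate.quad(f, 0.0, 1.0, epsabs=1e-12, epsrel=1e-10, limit=200)
    return beta * (beta - 1.0) * val


def _mixed_const(beta: float) -> float:
    """L(β) = β∫₀¹ t(1−t)^{β−2} ln t dt = E[t ln t/(1−t)] (negative)."""
    if beta > 1.0:
        return float(
            beta * special.beta(2.0, beta - 1.0) * (_PSI2 - special.digamma(beta + 1.0))
        )

    def f(t: float) -> float:
        return t * (1.0 - t) ** (beta - 2.0) * np.log(t)

    val, _ = integrate.quad(f, 0.0, 1.0, epsabs=1e-12, epsrel=1e-10, limit=200)
    return beta * val


def expected_information(theta: ModelParams, n: int, m: int) -> InfoMatrix:
    """Expected Fisher information J(θ) for sample sizes (n, m)."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    a, b1, b2 = theta.alpha, theta.beta1, theta.beta2
    j11 = (n + m + n * _curvature_const(b1) + m * _curvature_const(b2)) / a**2
    j12 = n * _mixed_const(b1) / a
    j13 = m * _mixed_const(b2) / a
    ent = np.array(
        [
            [j11, j12, j13],
            [j12, n / b1**2, 0.0],
            [j13, 0.0, m / b2**2],
        ]
    )
    return InfoMatrix(ent, "expected")


def covariance(J: InfoMatrix) -> np.ndarray:
    """Σ = J⁻¹ by explicit 3×3 cofactor expansion (J₂₃ = 0 structure kept)."""
    e = J.entries
    det = (
        e[0, 0] * (e[1, 1] * e[2, 2] - e[1, 2] * e[2, 1])
        - e[0, 1] * (e[1, 0] * e[2, 2] - e[1, 2] * e[2, 0])
        + e[0, 2] * (e[1, 0] * e[2, 1] - e[1, 1] * e[2, 0])
    )
    if det <= 0 or not np.isfinite(det):
        cond = np.linalg.cond(e)
        raise np.linalg.LinAlgError(
            f"information matrix not positive definite (det={det:g}, cond={cond:g})"
        )
    cof = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            minor = np.delete(np.delete(e, i, axis=0), j, axis=1)
            cof[i, j] = (-1) ** (i + j) * (minor[0, 0] * minor[1, 1] - minor[0, 1] * minor[1, 0])
    return cof.T / det


def _threshold_cross(a: float, b: float, alpha: float) -> tuple[float, float, float]:
    """(a^α(1−b^α)ln a − b^α(1−a^α)ln b, 1−a^α, 1−b^α); a^α ln a → 0 at a=0."""
    aa = a**alpha
    bb = b**alpha
    ta = aa * (1.0 - bb) * np.log(a) if a > 0 else 0.0
    tb = bb * (1.0 - aa) * np.log(b) if b > 0 else 0.0
    return ta - tb, 1.0 - aa, 1.0 - bb


def delta_gradient(theta: ModelParams, t: Thresholds) -> np.ndarray:
    """Analytic gradient ġ of the closed-form R^{|a,b} in (α, β₁, β₂)."""
    b1, b2 = theta.beta1, theta.beta2
    s = b1 + b2
    if t.a == t.b:
        return np.array([0.0, -b2 / s**2, b1 / s**2])
    cross, one_a, one_b = _threshold_cross(t.a, t.b, theta.alpha)
    if t.a < t.b:
        q = one_b / one_a
        rho1 = b1 * b2 / s * q ** (b1 - 1.0) * cross / one_a**2
        rho2 = b2 / s * q**b1 * (np.log(q) - 1.0 / s)
        rho3 = b1 / s**2 * q**b1
        return np.array([rho1, rho2, rho3])
    sfac = one_a / one_b
    gam1 = b1 * b2 / s * sfac ** (b2 - 1.0) * cross / one_b**2
    gam2 = -b2 / s**2 * sfac**b2
    gam3 = b1 / s * sfac**b2 * (1.0 / s - np.log(sfac))
    return np.array([gam1, gam2, gam3])


def _expanded_sigma_sq(
    theta: ModelParams, t: Thresholds, n: int, m: int, grad: np.ndarray
) -> tuple[float | None, dict]:
    """Scalar closed-form variance through the A/C/D aggregates (β's > 2 only)."""
    a, b1, b2 = theta.alpha, theta.beta1, theta.beta2
    if b1 <= 2.0 or b2 <= 2.0:
        return None, {}
    B1 = float(special.beta(2.0, b1 - 2.0))
    B2 = float(special.beta(2.0, b2 - 2.0))
    B3 = float(special.beta(2.0, b2 - 1.0))
    B4 = float(special.beta(2.0, b1 - 1.0))
    psi1 = _PSI2 - float(special.digamma(b1))
    psi2 = _PSI2 - float(special.digamma(b2))
    psi3 = _PSI2 - float(special.digamma(b2 + 1.0))
    psi4 = _PSI2 - float(special.digamma(b1 + 1.0))
    psi1p = _PSI2P - float(special.polygamma(1, b1))
    psi2p = _PSI2P - float(special.polygamma(1, b2))
    A = n + m + n * b1 * (b1 - 1.0) * B1 * (psi1**2 + psi1p) + m * b2 * (b2 - 1.0) * B2 * (
        psi2**2 + psi2p
    )
    C = m * b2**4 * B3**2 * psi3**2
    D = n * b1**4 * B4**2 * psi4**2
    denom = A - C - D
    g1, g2, g3 = grad
    sig = (
        g1**2 * a**2
        + g2**2 * b1**2 * (A - C) / n
        + g3**2 * b2**2 * (A - D) / m
        - 2.0 * g1 * g2 * a * b1**3 * B4 * psi4
        - 2.0 * g1 * g3 * a * b2**3 * B3 * psi3
        + 2.0 * g2 * g3 * b1**3 * b2**3 * B3 * B4 * psi3 * psi4
    ) / denom
    consts = dict(
        B1=B1, B2=B2, B3=B3, B4=B4,
        psi1=psi1, psi2=psi2, psi3=psi3, psi4=psi4,
        psi1p=psi1p, psi2p=psi2p, A=A, C=C, D=D,
    )
    return float(sig), consts


def r_variance(theta: ModelParams, t: Thresholds, n: int, m: int) -> DeltaComponents:
    """Delta-method variance of R̂^{|a,b} at θ for sample sizes (n, m)."""
    if n < 2 or m < 2:
        raise ValueError("n and m must be >= 2 for a nondegenerate variance")
    grad = delta_gradient(theta, t)
    sigma = covariance(expected_information(theta, n, m))
    sigma_sq = float(grad @ sigma @ grad)
    case = "a=b" if t.a == t.b else ("a<b" if t.a < t.b else "a>b")
    expanded, consts = _expanded_sigma_sq(theta, t, n, m, grad)
    return DeltaComponents(
        case=case,
        grad=grad,
        sigma=sigma,
        sigma_sq=sigma_sq,
        sigma_sq_expanded=expanded,
        constants=consts,
    )


def wald_interval(r_hat: float, sigma_hat: float, level: float) -> WaldInterval:
    """r̂ ∓ z_{(1+level)/2}·σ̂.  Not clipped to [0,1]; clip downstream if wanted."""
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    if sigma_hat < 0:
        raise ValueError("sigma_hat must be nonnegative")
    z = float(stats.norm.ppf(0.5 * (1.0 + level)))
    return WaldInterval(
        lower=r_hat - z * sigma_hat,
        upper=r_hat + z * sigma_hat,
        level=level,
        se=sigma_hat,
    )
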