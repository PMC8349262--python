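"""Profile maximum likelihood for the shared-α two-sample Kumaraswamy model.

Given x₁..xₙ ~ Ku(α, β₁) and y₁..yₘ ~ Ku(α, β₂), the log-likelihood is

    ℓ(α, β₁, β₂) = (n+m)ln α + n ln β₁ + m ln β₂
                   + (α−1)(lx + ly) + (β₁−1)·lxx(α) + (β₂−1)·lyy(α)

with lx = Σ ln xᵢ, lxx(α) = Σ ln(1 − xᵢ^α) (and likewise for y).  For fixed
α the β's maximise in closed form, β̂₁(α) = −n/lxx(α), β̂₂(α) = −m/lyy(α),
so fitting reduces to a one-dimensional root problem in α: the profile score

    s(α) = (n+m)/α + lx + ly
           − (β̂₁(α)−1) Σ xᵢ^α ln xᵢ/(1−xᵢ^α)
           − (β̂₂(α)−1) Σ yⱼ^α ln yⱼ/(1−yⱼ^α)

diverges to +∞ as α→0⁺ and is eventually negative, so a bracketed solver
(Brent) is robust.  The plug-in reliability estimate feeds the fitted triple
— including α̂ inside the threshold factors — through the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .distribution import KwParams
from .reliability import ModelParams, Thresholds, conditional_reliability

__all__ = [
    "TwoSampleData",
    "MleResult",
    "log_likelihood",
    "profile_betas",
    "alpha_score",
    "fit_mle",
    "estimate_R",
]

_BRACKET_FLOOR = 1e-6
_BRACKET_CEIL = 1e6


class FitError(RuntimeError):
    """Raised when the profile score has no bracketed root."""


@dataclass(frozen=True)
class TwoSampleData:
    """Stress sample x (size n) and strength sample y (size m).

    Every observation must lie strictly inside (0, 1) — the likelihood
    involves ln x and ln(1 − x^α), both undefined at the endpoints.  Data on
    the boundary are rejected, never clipped: silent clipping would bias the
    β estimates.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        for name, v in (("x", self.x), ("y", self.y)):
            if v.ndim != 1 or v.size < 2:
                raise ValueError(f"sample {name} must be a 1-d array with at least 2 values")
            if np.any((v <= 0.0) | (v >= 1.0)):
                raise ValueError("values must lie strictly in (0, 1)")
        object.__setattr__(self, "_log_x", np.log(self.x))
        object.__setattr__(self, "_log_y", np.log(self.y))

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def m(self) -> int:
        return self.y.size

    @property
    def lx(self) -> float:
        return float(self._log_x.sum())

    @property
    def ly(self) -> float:
        return float(self._log_y.sum())

    def lxx(self, alpha: float) -> float:
        """Σ ln(1 − xᵢ^α), computed through log1p(−exp(α ln x))."""
        return float(np.log1p(-np.exp(alpha * self._log_x)).sum())

    def lyy(self, alpha: float) -> float:
        return float(np.log1p(-np.exp(alpha * self._log_y)).sum())

    def _score_sums(self, alpha: float) -> tuple[float, float]:
        """(Σ x^α ln x/(1−x^α), Σ y^α ln y/(1−y^α))."""
        tx = np.exp(alpha * self._log_x)
        ty = np.exp(alpha * self._log_y)
        sx = float((tx * self._log_x / (1.0 - tx)).sum())
        sy = float((ty * self._log_y / (1.0 - ty)).sum())
        return sx, sy


@dataclass(frozen=True)
class MleResult:
    theta_hat: ModelParams
    loglik: float
    score_residual: float
    converged: bool

    @property
    def alpha(self) -> float:
        return self.theta_hat.alpha

    @property
    def beta1(self) -> float:
        return self.theta_hat.beta1

    @property
    def beta2(self) -> float:
        return self.theta_hat.beta2


def log_likelihood(theta: ModelParams, d: TwoSampleData) -> float:
    """Joint log-likelihood of both samples at θ = (α, β₁, β₂)."""
    a, b1, b2 = theta.alpha, theta.beta1, theta.beta2
    return (
        (d.n + d.m) * np.log(a)
        + d.n * np.log(b1)
        + d.m * np.log(b2)
        + (a - 1.0) * (d.lx + d.ly)
        + (b1 - 1.0) * d.lxx(a)
        + (b2 - 1.0) * d.lyy(a)
    )


def profile_betas(alpha: float, d: TwoSampleData) -> tuple[float, float]:
    """Closed-form conditional maximisers (β̂₁, β̂₂) = (−n/lxx, −m/lyy)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    lxx, lyy = d.lxx(alpha), d.lyy(alpha)
    if lxx == 0.0 or lyy == 0.0:
        raise ZeroDivisionError("degenerate data: log(1 - x^alpha) sums to zero")
    return -d.n / lxx, -d.m / lyy


def alpha_score(alpha: float, d: TwoSampleData) -> float:
    """Profile score dℓ*/dα with β̂₁(α), β̂₂(α) substituted.

    By the envelope theorem this equals ∂ℓ/∂α evaluated at (α, β̂₁(α), β̂₂(α)).
    """
    b1, b2 = profile_betas(alpha, d)
    sx, sy = d._score_sums(alpha)
    return (d.n + d.m) / alpha + d.lx + d.ly - (b1 - 1.0) * sx - (b2 - 1.0) * sy


def _profile_loglik(alpha: float, d: TwoSampleData) -> float:
    b1, b2 = profile_betas(alpha, d)
    return log_likelihood(ModelParams(alpha, b1, b2), d)


def fit_mle(d: TwoSampleData, xtol: float = 1e-12) -> MleResult:
    """Fit (α̂, β̂₁, β̂₂) by bracketed root-finding on the profile score.

    The initial bracket [0.1, 10] is expanded geometrically until the score
    changes sign; should distinct sign changes appear during expansion, the
    root with the highest profiled log-likelihood wins (the MLE is defined
    by the maximum, not by the root).
    """
    lo, hi = 0.1, 10.0
    s_lo, s_hi = alpha_score(lo, d), alpha_score(hi, d)
    while s_lo <= 0 and lo > _BRACKET_FLOOR:
        lo /= 4.0
        s_lo = alpha_score(lo, d)
    while s_hi >= 0 and hi < _BRACKET_CEIL:
        hi *= 4.0
        s_hi = alpha_score(hi, d)
    if s_lo <= 0 or s_hi >= 0:
        raise FitError(
            "no sign change of the profile score on "
            f"[{lo:g}, {hi:g}] (score: {s_lo:g}, {s_hi:g})"
        )
    alpha_hat = optimize.brentq(alpha_score, lo, hi, args=(d,), xtol=xtol)
    b1, b2 = profile_betas(alpha_hat, d)
    theta = ModelParams(alpha_hat, b1, b2)
    resid = alpha_score(alpha_hat, d)
    return MleResult(
        theta_hat=theta,
        loglik=log_likelihood(theta, d),
        score_residual=resid,
        converged=abs(resid) < 1e-6 * (d.n + d.m),
    )


def estimate_R(result: MleResult, t: Thresholds) -> float:
    """Plug-in estimate of R^{|a,b} at the fitted triple."""
    if not result.converged:
        raise ValueError("MLE did not converge; refusing to compute plug-in estimate")
    return conditional_reliability(result.theta_hat, t)
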