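"""Kumaraswamy distribution primitives.

The Kumaraswamy law Ku(α, β) lives on (0, 1) with closed-form cdf
``F(x) = 1 − (1 − x^α)^β``.  Both shape parameters are strictly positive.
Because the cdf inverts in closed form, sampling is done by inversion — one
uniform per draw, exact and reproducible.

Powers ``x^α`` are evaluated as ``exp(α·ln x)`` and ``ln(1 − x^α)`` as
``log1p(−exp(α·ln x))`` so that large α and small x do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KwParams", "kw_pdf", "kw_cdf", "kw_quantile", "kw_sample"]


@dataclass(frozen=True)
class KwParams:
    """Shape-parameter pair (α, β) of a Kumaraswamy law."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"Kumaraswamy shapes must be strictly positive, got "
                f"alpha={self.alpha}, beta={self.beta}"
            )


def _check_unit(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def kw_pdf(x, p: KwParams):
    """Density α β x^{α−1} (1−x^α)^{β−1} on [0, 1].

    At the endpoints the density can be singular (α<1 at 0, β<1 at 1);
    those points return ``inf`` rather than raising so that quadrature
    over the open interval remains usable.
    """
    x = _check_unit(x, "x")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        xa = np.exp(p.alpha * np.log(x, where=x > 0, out=np.full_like(x, -np.inf)))
        out = p.alpha * p.beta * np.power(x, p.alpha - 1) * np.power(1 - xa, p.beta - 1)
    # interior values are always finite; endpoints may be 0, finite or inf
    if out.ndim == 0:
        return float(out)
    return out


def kw_cdf(x, p: KwParams):
    """Distribution function 1 − (1−x^α)^β, evaluated in log space."""
    x = _check_unit(x, "x")
    with np.errstate(divide="ignore"):
        log_x = np.log(x, where=x > 0, out=np.full_like(x, -np.inf))
        log_sf = p.beta * np.log1p(-np.exp(p.alpha * log_x))
    out = -np.expm1(log_sf)
    if out.ndim == 0:
        return float(out)
    return out


def kw_quantile(u, p: KwParams):
    """Inverse cdf: (1 − (1−u)^{1/β})^{1/α}."""
    u = _check_unit(u, "u")
    out = np.power(-np.expm1(np.log1p(-u) / p.beta), 1.0 / p.alpha)
    if out.ndim == 0:
        return float(out)
    return out


def kw_sample(size: int, p: KwParams, seed) -> np.ndarray:
    """Draw i.i.d. Kumaraswamy variates by inversion.

    Parameters
    ----------
    size : number of draws (≥ 1).
    p : shape parameters.
    seed : int seed or an existing :class:`numpy.random.Generator`; with an
        int seed the same vector is returned on every call.

    Returns values strictly inside (0, 1): uniforms are drawn from the open
    interval so neither endpoint can occur.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # open-interval uniforms: random() is in [0, 1); shift off exact 0
    u = rng.random(size)
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
    v = np.asarray(kw_quantile(u, p))
    # extreme shapes can round the quantile to an endpoint in double
    # precision; pin to the nearest representable interior value
    return np.clip(v, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
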