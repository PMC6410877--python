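"""Closed-form distance distributions for two-color colocalization.

When two fluorophores separated by a true distance ``mu`` are each localized
with isotropic Gaussian error, the measured 2D Euclidean separation ``r``
follows the radial distribution

    p(r | mu, sigma_d) = (r / sigma_d^2)
                         * exp(-(mu^2 + r^2) / (2 sigma_d^2))
                         * I0(r mu / sigma_d^2)

where ``sigma_d`` is the per-axis standard deviation of the separation error
and ``I0`` the modified Bessel function of order zero.  Mathematically this is
the Rice distribution with location ``mu`` and scale ``sigma_d``; in the
single-molecule colocalization literature it is known as the 2D probability
distribution (P2D).  Two limits matter in practice: for ``mu = 0`` it reduces
exactly to a Rayleigh density, and for ``mu / sigma_d -> 0`` it becomes
independent of ``mu`` altogether, which is the root cause of the ill-posedness
of the two-parameter maximum-likelihood fit at small distances.

All densities are evaluated in log space using the exponentially scaled Bessel
function so that they stay finite where the textbook expression overflows
(``r mu / sigma_d^2`` beyond ~700).  A clamp to the floating-point extremes is
retained as a final guard on the linear-scale density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

__all__ = [
    "P2DParams",
    "p2d_pdf",
    "p2d_pdf_approx",
    "p2d_logpdf",
    "p2d_cdf",
]

_FLOAT_MAX = np.finfo(float).max
_FLOAT_TINY = np.finfo(float).tiny
#: integration tolerance of the CDF quadrature (the CDF is defined by numeric
#: integration of the density; this is the absolute tolerance we request)
CDF_QUAD_TOL = 1e-10
#: half-width, in units of sigma_d, of the interval around mu that carries all
#: practical probability mass (Gaussian tail beyond 12 sigma is < 2e-33)
_TAIL_SIGMAS = 12.0


@dataclass(frozen=True)
class P2DParams:
    """Parameters of the measured-distance distribution.

    Attributes
    ----------
    mu:
        True (or estimated) separation in nm; non-negative.
    sigma_d:
        Distance uncertainty in nm (per-axis SD of the separation error);
        strictly positive.
    """

    mu: float
    sigma_d: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or self.mu < 0:
            raise ValueError(f"mu must be finite and >= 0, got {self.mu}")
        if not np.isfinite(self.sigma_d) or self.sigma_d <= 0:
            raise ValueError(
                f"sigma_d must be finite and > 0, got {self.sigma_d}"
            )


def _logpdf(r, mu, sigma):
    """Log of the P2D density, vectorized, numerically stable.

    Uses log I0(z) = log i0e(z) + z, which turns the Gaussian-times-Bessel
    product into exp(-(r-mu)^2 / (2 sigma^2)) times a slowly varying factor.
    Returns -inf at r = 0 (and for r < 0); no domain checks here.
    """
    r = np.asarray(r, dtype=float)
    z = r * mu / sigma**2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            np.log(r)
            - 2.0 * np.log(sigma)
            - (r - mu) ** 2 / (2.0 * sigma**2)
            + np.log(special.i0e(z))
        )
    return np.where(r > 0, out, -np.inf)


def _logpdf_approx(r, mu, sigma):
    """Log of the Gaussian approximation to the P2D (valid for sigma << mu).

    log[ 1/sqrt(2 pi sigma^2) * sqrt(r/mu) * exp(-(r-mu)^2 / (2 sigma^2)) ]
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            -0.5 * np.log(2.0 * np.pi * sigma**2)
            + 0.5 * (np.log(r) - np.log(mu))
            - (r - mu) ** 2 / (2.0 * sigma**2)
        )
    return np.where(r > 0, out, -np.inf)


def _check_r(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValueError("r must be finite and >= 0")
    return r


def p2d_pdf(r, params: P2DParams):
    """Density of the measured distance ``r`` (1/nm).

    Evaluated in log space; the result is clamped into the representable
    floating-point range so it is never NaN or infinite for valid inputs.
    """
    r = _check_r(r)
    with np.errstate(over="ignore"):
        out = np.exp(_logpdf(r, params.mu, params.sigma_d))
    out = np.clip(out, 0.0, _FLOAT_MAX)
    return out if out.ndim else float(out)


def p2d_pdf_approx(r, params: P2DParams):
    """Gaussian approximation to :func:`p2d_pdf`, accurate for sigma_d < mu/2.

    Raises for mu = 0 (the form divides by mu).
    """
    if params.mu <= 0:
        raise ValueError("the Gaussian approximation requires mu > 0")
    r = _check_r(r)
    with np.errstate(over="ignore"):
        out = np.exp(_logpdf_approx(r, params.mu, params.sigma_d))
    out = np.clip(out, 0.0, _FLOAT_MAX)
    return out if out.ndim else float(out)


def p2d_logpdf(r, params: P2DParams):
    """Log-density; finite wherever the linear-scale form would overflow."""
    r = _check_r(r)
    out = _logpdf(r, params.mu, params.sigma_d)
    return out if out.ndim else float(out)


def p2d_cdf(r, params: P2DParams):
    """Cumulative probability P(R <= r), by adaptive quadrature of the density.

    The integrand is restricted to the interval of practical mass
    [max(0, mu - 12 sigma_d), mu + 12 sigma_d]; outside it the Gaussian factor
    is below 1e-30, which we treat as an analytic tail bound of 0 below and 1
    above.
    """
    r = np.asarray(r, dtype=float)
    _check_r(r)
    mu, sigma = params.mu, params.sigma_d
    lo = max(0.0, mu - _TAIL_SIGMAS * sigma)
    hi_mass = mu + _TAIL_SIGMAS * sigma

    def _one(ri: float) -> float:
        if ri <= lo:
            return 0.0
        upper = min(ri, hi_mass)
        val, _ = integrate.quad(
            lambda t: np.exp(_logpdf(t, mu, sigma)),
            lo,
            upper,
            epsabs=CDF_QUAD_TOL,
            epsrel=1e-10,
            limit=200,
        )
        return float(np.clip(val, 0.0, 1.0))

    out = np.vectorize(_one, otypes=[float])(r)
    return out if out.ndim else float(out)
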