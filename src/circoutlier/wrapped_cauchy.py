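"""The wrapped-Cauchy (WC) distribution on the circle.

A Cauchy variate with location ``mu`` and scale ``gamma`` wrapped mod
``2*pi`` follows WC(``mu``, ``rho``) with concentration ``rho = exp(-gamma)``.
The density has the closed form

    f(theta) = (1 - rho^2) / (2*pi * (1 + rho^2 - 2*rho*cos(theta - mu)))

with ``rho in [0, 1)``: ``rho = 0`` is the circular uniform distribution and
``rho -> 1`` concentrates all mass at ``mu``.  The family is heavy-tailed
relative to the von Mises distribution, which is what makes median-based
residual diagnostics attractive for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .angles import TWO_PI, mean_direction, resultant_length, wrap
from .exceptions import InvalidParameterError

__all__ = ["WCParams", "wc_density", "wc_cdf", "sample_wc", "fit_wc"]

_RHO_CEIL = 1.0 - 1e-9


@dataclass(frozen=True)
class WCParams:
    """Wrapped-Cauchy parameters: mean direction ``mu`` (radians) and concentration ``rho``."""

    mu: float
    rho: float

    def __post_init__(self):
        if not np.isfinite(self.mu):
            raise InvalidParameterError("mu must be finite")
        if not (0.0 <= self.rho < 1.0):
            raise InvalidParameterError(f"rho must lie in [0, 1), got {self.rho}")
        object.__setattr__(self, "mu", float(wrap(self.mu)))
        object.__setattr__(self, "rho", float(self.rho))


def wc_density(theta, params: WCParams) -> np.ndarray:
    """WC probability density, elementwise over ``theta`` (any real angles)."""
    z = wrap(theta) - params.mu
    rho = params.rho
    return (1.0 - rho**2) / (TWO_PI * (1.0 + rho**2 - 2.0 * rho * np.cos(z)))


def _cdf_from_antipode(theta, params: WCParams) -> np.ndarray:
    """CDF measured from the antipode ``mu - pi``; closed form via the half-angle map."""
    # signed angle from mu, in [-pi, pi): the anchor mu - pi maps to -pi (F = 0)
    psi = np.mod(wrap(np.asarray(theta, dtype=float) - params.mu) + np.pi, TWO_PI) - np.pi
    if params.rho == 0.0:
        return (psi + np.pi) / TWO_PI
    k = (1.0 + params.rho) / (1.0 - params.rho)
    return 0.5 + np.arctan(k * np.tan(psi / 2.0)) / np.pi


def wc_cdf(theta, params: WCParams, start: float | None = None) -> np.ndarray:
    """WC distribution function as arc-length probability from a reference angle.

    By default the reference (zero-probability) point is the antipode
    ``mu - pi``, where the density is smallest.  Any other ``start`` angle
    may be given; the returned values are the probability mass on the
    counter-clockwise arc from ``start`` to ``theta``, in ``[0, 1)``.
    """
    f = _cdf_from_antipode(theta, params)
    if start is None:
        return f
    f0 = _cdf_from_antipode(start, params)
    return np.mod(f - f0, 1.0)


def sample_wc(n: int, params: WCParams, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. WC angles by wrapping Cauchy(mu, -log(rho)) mod 2*pi.

    ``seed`` may be an integer seed or a ``numpy.random.Generator``;
    ``rho = 0`` draws from the circular uniform distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if params.rho == 0.0:
        return rng.uniform(0.0, TWO_PI, size=n)
    scale = -np.log(params.rho)
    return wrap(params.mu + scale * rng.standard_cauchy(n))


def _negative_loglik(mu: float, rho: float, angles: np.ndarray) -> float:
    dens = wc_density(angles, WCParams(mu, rho))
    return -float(np.sum(np.log(dens)))


def fit_wc(angles, method: str = "moment") -> WCParams:
    """Estimate WC parameters from a sample.

    The default moment estimator sets ``mu`` to the mean direction and
    ``rho`` to the mean resultant length (for WC, ``E[cos(theta - mu)] = rho``).
    ``method='mle'`` refines both by direct likelihood maximization from the
    moment start.  ``rho`` is clipped below 1 so the result is always a
    valid parameter set.
    """
    a = wrap(np.atleast_1d(angles))
    if a.size < 2:
        raise ValueError("need at least two angles to fit")
    mu = mean_direction(a)  # raises UndefinedDirectionError on zero resultant
    rho = min(resultant_length(a), _RHO_CEIL)
    if method == "moment":
        return WCParams(mu, rho)
    if method != "mle":
        raise ValueError(f"unknown method: {method!r}")

    # likelihood surface is smooth in (mu, logit rho); moment start is close
    def nll(v):
        m, eta = v
        r = 1.0 / (1.0 + np.exp(-eta))
        return _negative_loglik(m, min(r, _RHO_CEIL), a)

    eta0 = np.log(max(rho, 1e-6) / max(1.0 - rho, 1e-12))
    res = optimize.minimize(nll, x0=[mu, eta0], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    mu_hat = float(wrap(res.x[0]))
    rho_hat = float(min(1.0 / (1.0 + np.exp(-res.x[1])), _RHO_CEIL))
    return WCParams(mu_hat, rho_hat)
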