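"""Circular-statistics primitives.

Angles live on the unit circle and are stored in radians, reduced to the
canonical range ``[0, 2*pi)``.  Ordinary arithmetic is invalid for such
data: the shortest arc between 0.1 and ``2*pi - 0.1`` has length 0.2, and
the sample mean of the raw numbers is replaced by the direction of the
resultant vector.  This module provides the distance, location and
dispersion measures everything else in the package is built on.
"""

from __future__ import annotations

import numpy as np

from .exceptions import UndefinedDirectionError

TWO_PI = 2.0 * np.pi

__all__ = [
    "TWO_PI",
    "wrap",
    "to_radians",
    "to_degrees",
    "circ_distance",
    "mean_direction",
    "resultant_length",
    "circular_median",
    "median_distance_objective",
]


def wrap(angles) -> np.ndarray:
    """Reduce angles (radians) into the canonical range ``[0, 2*pi)``.

    Accepts scalars or arrays of any real value; the reduction is
    idempotent.  Non-finite input raises ``ValueError``.
    """
    a = np.asarray(angles, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    r = np.mod(a, TWO_PI)
    # guard against float round-up of tiny negative inputs
    r = np.where(r >= TWO_PI, r - TWO_PI, r)
    return r


def to_radians(values, units: str = "radians") -> np.ndarray:
    """Convert angle values to wrapped radians. ``units`` is 'degrees' or 'radians'."""
    v = np.asarray(values, dtype=float)
    if units == "degrees":
        v = np.deg2rad(v)
    elif units != "radians":
        raise ValueError(f"unknown angle units: {units!r}")
    return wrap(v)


def to_degrees(angles) -> np.ndarray:
    """Convert wrapped radians to degrees in ``[0, 360)``."""
    return np.rad2deg(wrap(angles))


def circ_distance(a, b) -> np.ndarray:
    """Shortest arc length between two angles: ``pi - |pi - |a - b||``.

    Symmetric, bounded in ``[0, pi]``, broadcasts elementwise over arrays.
    Inputs are reduced mod ``2*pi`` internally, so any finite real values
    are accepted.
    """
    d = np.abs(wrap(a) - wrap(b))
    return np.pi - np.abs(np.pi - d)


def _resultant_components(angles) -> tuple[np.ndarray, float, float]:
    a = wrap(angles)
    if a.size == 0:
        raise ValueError("empty angle array")
    return a, float(np.sum(np.sin(a))), float(np.sum(np.cos(a)))


def mean_direction(angles) -> float:
    """Direction of the resultant vector: ``atan2(sum sin, sum cos)`` in ``[0, 2*pi)``.

    Raises
    ------
    UndefinedDirectionError
        If the resultant vector is (numerically) zero, e.g. for angles
        placed antipodally so that the sine and cosine sums both cancel.
    """
    a, s, c = _resultant_components(angles)
    if np.hypot(s, c) < 1e-12 * a.size:
        raise UndefinedDirectionError("zero resultant: mean direction undefined")
    return float(wrap(np.arctan2(s, c)))


def resultant_length(angles) -> float:
    """Mean resultant length ``R`` in ``[0, 1]``: 1 for a point mass, 0 under cancellation."""
    a, s, c = _resultant_components(angles)
    return float(np.hypot(s, c) / a.size)


def median_distance_objective(theta, angles) -> np.ndarray:
    """Mean circular distance from candidate angle(s) ``theta`` to the sample."""
    a = wrap(angles)
    t = np.atleast_1d(wrap(theta))
    return circ_distance(t[:, None], a[None, :]).mean(axis=1)


def circular_median(angles) -> float:
    """Sample circular median: the observation minimizing the mean circular distance.

    The minimizer of the mean-arc-distance objective over the whole circle
    is attained at a data point for odd sample sizes; restricting the
    candidate set to the observations makes the estimator finite and
    deterministic for even sizes too.  Ties are broken by the smallest
    angle in ``[0, 2*pi)``.
    """
    a = wrap(np.atleast_1d(angles))
    if a.size == 0:
        raise ValueError("empty angle array")
    obj = median_distance_objective(a, a)
    # primary key: objective; secondary key: the angle itself
    best = np.lexsort((a, obj))[0]
    return float(a[best])
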