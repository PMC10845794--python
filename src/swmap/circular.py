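"""Circular statistics on the 180-degree orientation circle.

Orientations (Gabor tilts) live on a half-circle: 0 and 180 degrees are the
same stimulus.  All angular arithmetic therefore runs on the doubled angle
``2*theta``, where the orientation circle maps onto the full circle and the
ordinary circular mean applies.  Signed differences are "acute angle
differences": the smallest rotation from one orientation to the other,
constrained to [-90, 90).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "acute_angle_diff",
    "circular_mean_orientation",
    "orientation_resultant",
    "fold_orientation",
    "wrap_orientation",
    "UndefinedMeanError",
]


class UndefinedMeanError(ValueError):
    """Raised when the circular mean of a set of orientations is undefined.

    This happens when the doubled-angle resultant vector has (numerically)
    zero length, e.g. for the balanced pair {0, 90} degrees.
    """


def wrap_orientation(theta):
    """Reduce orientations into [0, 180)."""
    return np.mod(theta, 180.0)


def acute_angle_diff(a, b):
    """Signed acute difference ``a - b`` on the orientation circle.

    Returns values in [-90, 90); exact perpendicularity maps to -90 (the
    half-open-interval boundary convention).  Broadcasts like ``a - b``.

    >>> acute_angle_diff(10, 170)
    20.0
    """
    return np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 90.0, 180.0) - 90.0


def orientation_resultant(thetas, axis=None, weights=None):
    """Doubled-angle resultant of a set of orientations.

    Returns ``(mean_orientation, resultant_length)`` where the mean is in
    [0, 180) and the length is in [0, 1] (1 = all orientations identical).
    No degeneracy check is performed; see :func:`circular_mean_orientation`.
    """
    th = np.deg2rad(2.0 * np.asarray(thetas, dtype=float))
    if weights is None:
        c = np.mean(np.cos(th), axis=axis)
        s = np.mean(np.sin(th), axis=axis)
    else:
        w = np.asarray(weights, dtype=float)
        wsum = np.sum(w, axis=axis)
        c = np.sum(w * np.cos(th), axis=axis) / wsum
        s = np.sum(w * np.sin(th), axis=axis) / wsum
    mean = np.mod(np.rad2deg(np.arctan2(s, c)) / 2.0, 180.0)
    return mean, np.hypot(c, s)


def circular_mean_orientation(thetas, axis=None, weights=None, tol=1e-9):
    """Circular mean of orientations via the doubled-angle method.

    Raises :class:`UndefinedMeanError` if any requested mean has a resultant
    length below ``tol`` (the mean direction is then arbitrary).
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise UndefinedMeanError("empty orientation set")
    mean, r = orientation_resultant(thetas, axis=axis, weights=weights)
    if np.any(np.asarray(r) < tol):
        raise UndefinedMeanError(
            "circular mean undefined: doubled-angle resultant length below tolerance"
        )
    return mean


def fold_orientation(theta):
    """Collapse orientations onto the [0, 90] cardinal-to-cardinal axis.

    ``theta`` if <= 90, else ``180 - theta``; i.e. the 90-180 range is
    reflected onto 0-90 so that both cardinals sit at the endpoints and the
    obliques coincide at 45.  Idempotent.
    """
    theta = np.asarray(theta, dtype=float)
    return np.where(theta <= 90.0, theta, 180.0 - theta)


def distance_to_oblique(theta):
    """Absolute acute distance (degrees, in [0, 45]) to the nearest oblique."""
    return np.abs(fold_orientation(wrap_orientation(theta)) - 45.0)


def distance_to_cardinal(theta):
    """Absolute acute distance (degrees, in [0, 45]) to the nearest cardinal."""
    f = fold_orientation(wrap_orientation(theta))
    return np.minimum(f, 90.0 - f)
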