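"""Circular descriptive statistics (degrees in, degrees out).

All computation is in radians internally; every public interface takes
and returns degrees, the scale on which TSNIT angles are reported.
"""

from __future__ import annotations

import numpy as np

RESULTANT_EPS = 1e-12


class UndefinedDirectionError(ValueError):
    """The resultant vector (or a variance term) vanishes."""


def _to_rad(deg) -> np.ndarray:
    return np.deg2rad(np.asarray(deg, dtype=float))


def circular_mean(angles_deg, weights=None) -> float:
    """(Weighted) circular mean direction, in [0, 360) degrees.

    The quadrant-specific inverse tangent of the weighted resultant
    vector (sum of w*sin over sum of w*cos).  Raises
    :class:`UndefinedDirectionError` when the resultant length is below
    1e-12 of the total weight (antipodal cancellation leaves no
    defined direction).
    """
    theta = _to_rad(angles_deg)
    if theta.size == 0:
        raise ValueError("need at least one angle")
    if weights is None:
        w = np.ones_like(theta)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != theta.shape:
            raise ValueError("angles and weights must have equal length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    s = float(np.sum(w * np.sin(theta)))
    c = float(np.sum(w * np.cos(theta)))
    if np.hypot(s, c) / total < RESULTANT_EPS:
        raise UndefinedDirectionError("resultant vector length is (numerically) zero")
    return float(np.rad2deg(np.arctan2(s, c)) % 360.0)


def resultant_length(angles_deg, weights=None) -> float:
    """Mean resultant length R-bar in [0, 1]."""
    theta = _to_rad(angles_deg)
    w = np.ones_like(theta) if weights is None else np.asarray(weights, dtype=float)
    s = np.sum(w * np.sin(theta))
    c = np.sum(w * np.cos(theta))
    return float(np.hypot(s, c) / w.sum())


def circular_difference(a_deg, b_deg) -> np.ndarray | float:
    """Signed smallest difference a - b, wrapped to (-180, 180]."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    out = np.where(d > 180.0, d - 360.0, d)
    return float(out) if out.ndim == 0 else out


def circular_correlation(a_deg, b_deg) -> float:
    """Circular analogue of Pearson's correlation for paired angles.

    The Jammalamadaka-SenGupta coefficient

        r = sum sin(a - a_mean) sin(b - b_mean)
            / sqrt(sum sin^2(a - a_mean) * sum sin^2(b - b_mean)),

    with circular means a_mean, b_mean; lies in [-1, 1].

    Raises
    ------
    UndefinedDirectionError
        If either series has zero circular variance (all sine
        deviations vanish) so the coefficient is undefined.
    """
    a = _to_rad(a_deg)
    b = _to_rad(b_deg)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D of equal length")
    if a.size < 2:
        raise ValueError("need at least two angle pairs")
    sa = np.sin(a - np.deg2rad(circular_mean(a_deg)))
    sb = np.sin(b - np.deg2rad(circular_mean(b_deg)))
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom < RESULTANT_EPS:
        raise UndefinedDirectionError("zero circular variance; correlation undefined")
    return float(np.clip(np.sum(sa * sb) / denom, -1.0, 1.0))
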