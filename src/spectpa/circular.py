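"""Circular (directional) helpers on angles in degrees.

Phases live on the cardiac cycle, a circle of 360 degrees; every mean,
difference and dispersion here must respect the wrap-around at 0/360.
"""

from __future__ import annotations

import numpy as np


def wrap360(angle_deg):
    """Map angles onto [0, 360), guarding the float edge case where a
    tiny negative angle wraps to exactly 360.0."""
    wrapped = np.asarray(angle_deg, dtype=float) % 360.0
    wrapped = np.where(wrapped >= 360.0, 0.0, wrapped)
    return float(wrapped) if np.ndim(angle_deg) == 0 else wrapped


def circular_mean(angles_deg, weights=None) -> float:
    """Weighted circular mean of angles, returned in [0, 360).

    Computed as atan2 of the weighted mean sine and cosine of the angles.

    Parameters
    ----------
    angles_deg : array-like
        Angles in degrees.
    weights : array-like, optional
        Non-negative weights, same length; default equal weights.

    Raises
    ------
    ValueError
        If the input is empty or the resultant vector has zero length
        (perfectly balanced angles have no defined mean direction).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("circular_mean of empty angle set")
    rad = np.deg2rad(a)
    if weights is None:
        s, c = np.sin(rad).mean(), np.cos(rad).mean()
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != a.shape:
            raise ValueError("weights must match angles in shape")
        tot = w.sum()
        if tot <= 0:
            raise ValueError("weights must have positive sum")
        s, c = (w * np.sin(rad)).sum() / tot, (w * np.cos(rad)).sum() / tot
    if np.hypot(s, c) < 1e-12:
        raise ValueError("mean direction undefined (zero resultant length)")
    return wrap360(float(np.rad2deg(np.arctan2(s, c))))


def circular_diff(a_deg, b_deg):
    """Signed circular difference a - b, wrapped to [-180, 180)."""
    return (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float) + 180.0) % 360.0 - 180.0


def circular_distance(a_deg, b_deg):
    """Absolute circular distance between angles, in [0, 180]."""
    return np.abs(circular_diff(a_deg, b_deg))


def circular_range(angles_deg) -> float:
    """Span of a set of angles on the circle, in degrees.

    Defined as 360 minus the largest gap between consecutive sorted
    angles; this equals the minimum over all rotations of (max - min),
    i.e. the width of the smallest arc containing every angle.
    """
    a = np.sort(np.asarray(angles_deg, dtype=float) % 360.0)
    if a.size == 0:
        raise ValueError("circular_range of empty angle set")
    if a.size == 1:
        return 0.0
    gaps = np.diff(a)
    wrap_gap = 360.0 - a[-1] + a[0]
    return float(360.0 - max(gaps.max(), wrap_gap))
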