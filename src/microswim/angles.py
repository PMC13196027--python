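"""Heading conventions and circular statistics helpers.

Convention used throughout: 0° points toward the top of the frame,
angles increase clockwise, range [0, 360). Image coordinates have y
increasing downward, so a heading θ maps to the unit displacement
(dx, dy) = (sin θ, −cos θ). "Straight down" (sedimentation) is 180°.
This matches polar plots drawn with the light source at the top.
"""

from __future__ import annotations

import numpy as np

DOWN_DEG = 180.0


def heading_from_vector(dx, dy):
    """Heading in degrees [0, 360) of displacement(s) (dx, dy), image coords."""
    return np.degrees(np.arctan2(dx, -np.asarray(dy, dtype=float))) % 360.0


def vector_from_heading(heading_deg, magnitude=1.0):
    """Displacement (dx, dy) in image coordinates for a heading in degrees."""
    rad = np.radians(heading_deg)
    return magnitude * np.sin(rad), -magnitude * np.cos(rad)


def angle_difference_deg(a, b):
    """Smallest absolute angular difference between two headings, in [0, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def circular_mean_deg(headings_deg):
    """Circular mean heading of a sample, degrees in [0, 360).

    Undefined (NaN) for an empty sample or perfectly cancelling headings
    whose resultant is numerically zero.
    """
    h = np.asarray(headings_deg, dtype=float)
    if h.size == 0:
        return float("nan")
    rad = np.radians(h)
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    if np.hypot(s, c) < 1e-12:
        return float("nan")
    return float(np.degrees(np.arctan2(s, c)) % 360.0)


def resultant_length(headings_deg) -> float:
    """Length of the mean unit vector: 1 = aligned, 0 = isotropic/cancelling."""
    h = np.asarray(headings_deg, dtype=float)
    if h.size == 0:
        return float("nan")
    rad = np.radians(h)
    return float(np.hypot(np.sin(rad).mean(), np.cos(rad).mean()))
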