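"""Shared coordinate and angle conventions.

Pixel coordinates are 0-based ``(row, col)`` with pixel centers on the
integer grid.  Physical positions are ``(x, y)`` in micrometres with
``x = col * pixel_size`` and ``y = row * pixel_size``.

Angles are reported in degrees in ``[0, 360)``.  Because image rows grow
downwards, the angle of a displacement ``(dx, dy)`` is evaluated on
``(dx, -dy)`` so that the visually counter-clockwise direction is
positive.  This one convention is used by every module; nothing else in
the package defines its own sign.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "vector_angle_deg", "unit_from_angle_deg"]


def wrap_deg(angles) -> np.ndarray | float:
    """Wrap angles (degrees) into ``[0, 360)``."""
    return np.mod(angles, 360.0)


def vector_angle_deg(dx, dy) -> np.ndarray | float:
    """Angle in degrees of displacement(s) ``(dx, dy)`` in image coordinates.

    ``(+1, 0)`` maps to 0 deg; ``(0, -1)`` (visually upward) maps to 90 deg.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    ang = np.degrees(np.arctan2(-dy, dx))
    return wrap_deg(ang)


def unit_from_angle_deg(angle_deg) -> np.ndarray:
    """Unit vector(s) ``(ux, uy)`` in image coordinates for angle(s) in degrees.

    Inverse of :func:`vector_angle_deg`: ``vector_angle_deg(*unit(a)) == a``.
    """
    rad = np.radians(np.asarray(angle_deg, dtype=float))
    return np.stack([np.cos(rad), -np.sin(rad)], axis=-1)
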