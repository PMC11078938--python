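"""Shared raster geometry helpers (ellipse interiors in image coordinates).

Coordinate convention across the package: (row, col), 0-based, origin at the
top-left pixel centre.  An ellipse orientation ``theta`` in [0, pi) is the
angle from the +row axis towards the +col axis of the major-axis direction,
so the unit vector along the major axis is (cos(theta), sin(theta)).
"""

from __future__ import annotations

import math

import numpy as np


def ellipse_interior(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_major: float,
    semi_minor: float,
    orientation: float,
) -> np.ndarray:
    """Boolean mask of pixels whose centres lie inside the ellipse.

    Parameters
    ----------
    shape
        (height, width) of the output mask.
    center
        (row, col) of the ellipse centre.
    semi_major, semi_minor
        Semi-axis lengths in pixels; ``semi_major >= semi_minor > 0``.
    orientation
        Major-axis angle in radians, see module docstring.
    """
    if semi_major <= 0 or semi_minor <= 0:
        raise ValueError("semi-axes must be positive")
    h, w = shape
    r0, c0 = center
    # Restrict computation to the bounding window of the ellipse.
    ext = semi_major + 1.0
    rlo = max(int(math.floor(r0 - ext)), 0)
    rhi = min(int(math.ceil(r0 + ext)) + 1, h)
    clo = max(int(math.floor(c0 - ext)), 0)
    chi = min(int(math.ceil(c0 + ext)) + 1, w)
    mask = np.zeros(shape, dtype=bool)
    if rlo >= rhi or clo >= chi:
        return mask
    rr = np.arange(rlo, rhi, dtype=float)[:, None] - r0
    cc = np.arange(clo, chi, dtype=float)[None, :] - c0
    ct, st = math.cos(orientation), math.sin(orientation)
    u = rr * ct + cc * st  # coordinate along the major axis
    v = -rr * st + cc * ct  # coordinate along the minor axis
    mask[rlo:rhi, clo:chi] = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
    return mask


def ellipse_area(semi_major: float, semi_minor: float) -> float:
    return math.pi * semi_major * semi_minor
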