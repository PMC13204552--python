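"""Sub-pixel sampling shared by scan-line and axial profiling."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates


def bilinear_sample(channel: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of ``channel`` at sub-pixel (row, col) points.

    Exact at integer pixel centers and on linear intensity ramps.  Points
    outside the image are clamped to the border value.
    """
    chan = np.asarray(channel, dtype=np.float64)
    coords = np.vstack([np.asarray(rows, float), np.asarray(cols, float)])
    return map_coordinates(chan, coords, order=1, mode="nearest")


def line_points(
    start: tuple[float, float],
    end: tuple[float, float],
    step_px: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced (rows, cols) along a segment, endpoint-inclusive.

    The spacing is the largest value <= ``step_px`` that divides the segment
    length evenly, so both endpoints are always sampled.
    """
    r0, c0 = start
    r1, c1 = end
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0.0:
        return np.array([r0]), np.array([c0])
    n = max(int(np.ceil(length / step_px)), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    return r0 + t * (r1 - r0), c0 + t * (c1 - c0)


def clip_chord_to_image(
    center: tuple[float, float],
    direction: tuple[float, float],
    shape: tuple[int, int],
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Full chord of the image rectangle through ``center`` along ``direction``.

    The rectangle is [0, H-1] x [0, W-1] in (row, col) pixel-center
    coordinates.  Returns the two endpoints ordered by increasing parameter.
    """
    h, w = shape
    cr, cc = center
    dr, dc = direction
    t_lo, t_hi = -np.inf, np.inf
    for c0, d, lim in ((cr, dr, h - 1), (cc, dc, w - 1)):
        if abs(d) < 1e-12:
            if not (0.0 <= c0 <= lim):
                raise ValueError("chord center outside image bounds")
            continue
        ta = (0.0 - c0) / d
        tb = (lim - c0) / d
        t_lo = max(t_lo, min(ta, tb))
        t_hi = min(t_hi, max(ta, tb))
    if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi <= t_lo:
        raise ValueError("degenerate chord")
    p0 = (cr + t_lo * dr, cc + t_lo * dc)
    p1 = (cr + t_hi * dr, cc + t_hi * dc)
    return p0, p1
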