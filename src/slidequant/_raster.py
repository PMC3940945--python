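"""Shared raster/physical-coordinate helpers.

Conventions used throughout the package:

* rasters are indexed ``[row, col]``; physical coordinates are ``(x, y)`` in
  millimetres with ``x`` along columns and ``y`` along rows;
* the centre of pixel ``[r, c]`` sits at ``((c + 0.5) * s, (r + 0.5) * s)``
  where ``s = mpp / 1000`` is the pixel pitch in mm;
* ``mpp`` is always microns per pixel.
"""

from __future__ import annotations

import numpy as np
import shapely


def mm_per_px(mpp: float) -> float:
    return mpp / 1000.0


def nearest_pixel(points_mm, shape, mpp):
    """Map ``(N, 2)`` x/y points in mm to (rows, cols) of nearest pixel centres.

    Points outside the raster are clipped to the border pixel.
    """
    s = mm_per_px(mpp)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    cols = np.clip(np.rint(pts[:, 0] / s - 0.5).astype(int), 0, shape[1] - 1)
    rows = np.clip(np.rint(pts[:, 1] / s - 0.5).astype(int), 0, shape[0] - 1)
    return rows, cols


def disk_kernel(radius_px: float) -> np.ndarray:
    """Boolean disk footprint: pixels whose centre lies within ``radius_px``."""
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (xx * xx + yy * yy) <= radius_px * radius_px


def circle_pixel_set(center_mm, radius_mm, shape, mpp) -> np.ndarray:
    """Boolean raster of pixels whose centre lies inside the given circle."""
    s = mm_per_px(mpp)
    cx, cy = center_mm
    r_px = radius_mm / s
    # circle centre expressed in (row, col) index coordinates
    c0 = cx / s - 0.5
    r0 = cy / s - 0.5
    dy = (np.arange(shape[0]) - r0)[:, None]
    dx = (np.arange(shape[1]) - c0)[None, :]
    return dy * dy + dx * dx <= r_px * r_px


def rasterize_polygon(poly, shape, mpp):
    """Rasterize a shapely polygon by pixel-centre containment.

    Returns ``(row_slice, col_slice, inside)`` restricted to the polygon's
    bounding box so callers can OR/paint into full-size accumulators without
    allocating a full raster per object.  ``inside`` may be empty when the
    polygon lies outside the raster.
    """
    s = mm_per_px(mpp)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx / s - 0.5)), 0)
    c1 = min(int(np.ceil(maxx / s - 0.5)), shape[1] - 1)
    r0 = max(int(np.floor(miny / s - 0.5)), 0)
    r1 = min(int(np.ceil(maxy / s - 0.5)), shape[0] - 1)
    if c1 < c0 or r1 < r0:
        empty = np.zeros((0, 0), dtype=bool)
        return slice(0, 0), slice(0, 0), empty
    xs = (np.arange(c0, c1 + 1) + 0.5) * s
    ys = (np.arange(r0, r1 + 1) + 0.5) * s
    X, Y = np.meshgrid(xs, ys)
    shapely.prepare(poly)
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    return slice(r0, r1 + 1), slice(c0, c1 + 1), inside
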