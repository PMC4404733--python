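"""Internal vector-geometry helpers: polygon moments, rasterization, angles."""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

TWO_PI = 2.0 * np.pi


def ang_dist(a: float, b: float) -> float:
    """Smallest absolute angular distance between two angles, in radians."""
    d = (a - b) % TWO_PI
    return min(d, TWO_PI - d)


def circular_mean(angles: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    """Weighted circular mean direction and resultant length.

    Returns (mean_angle, R) where R in [0, 1] is the mean resultant length
    (0 for a uniform angular distribution, 1 for a point mass).
    """
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        return 0.0, 0.0
    z = np.sum(weights * np.exp(1j * angles)) / total
    return float(np.angle(z)), float(np.abs(z))


def _ring_moments(coords: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Signed area, first and second moments of a closed ring (Green's theorem)."""
    x = coords[:, 0]
    y = coords[:, 1]
    x1 = np.roll(x, -1)
    y1 = np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    mx = np.sum((x + x1) * cross) / 6.0
    my = np.sum((y + y1) * cross) / 6.0
    # second moments about the origin: ixx = integral x^2 dA, etc.
    ixx = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    iyy = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    return a, mx, my, ixx, iyy, ixy


def polygon_moments(geom: BaseGeometry) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid, and central second-moment (covariance) matrix of a polygon.

    The covariance matrix is normalized per unit area, so a disc of radius R
    has eigenvalues R^2/4. Holes and multi-part geometries are handled.
    """
    polys: list[Polygon]
    if isinstance(geom, Polygon):
        polys = [geom]
    elif isinstance(geom, MultiPolygon):
        polys = list(geom.geoms)
    else:
        polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    a_tot = 0.0
    mx_tot = my_tot = 0.0
    ixx = iyy = ixy = 0.0
    for poly in polys:
        rings = [np.asarray(poly.exterior.coords)] + [
            np.asarray(r.coords) for r in poly.interiors
        ]
        for i, ring in enumerate(rings):
            a, mx, my, jxx, jyy, jxy = _ring_moments(ring)
            # exterior rings contribute with their signed orientation; a
            # correctly oriented polygon yields positive exterior area and
            # negative hole area automatically via the shoelace sign
            a_tot += a
            mx_tot += mx
            my_tot += my
            ixx += jxx
            iyy += jyy
            ixy += jxy
    if abs(a_tot) < 1e-300:
        return 0.0, np.zeros(2), np.zeros((2, 2))
    cx = mx_tot / a_tot
    cy = my_tot / a_tot
    sxx = ixx / a_tot - cx * cx
    syy = iyy / a_tot - cy * cy
    sxy = ixy / a_tot - cx * cy
    cov = np.array([[sxx, sxy], [sxy, syy]])
    return abs(a_tot), np.array([cx, cy]), cov


def polygon_roundness(geom: BaseGeometry) -> float:
    """Roundness 4*area / (pi * major_axis^2) from exact polygon moments.

    The major axis is that of the moments-equivalent ellipse (full length
    4*sqrt(lambda_max)), matching the ImageJ "fit ellipse" convention. A disc
    scores 1; elongated shapes score lower.
    """
    area, _, cov = polygon_moments(geom)
    if area <= 0:
        return float("nan")
    lam_max = float(np.linalg.eigvalsh(cov)[-1])
    if lam_max <= 0:
        return float("nan")
    major = 4.0 * np.sqrt(lam_max)
    return float(4.0 * area / (np.pi * major**2))


def rasterize(
    geom: BaseGeometry,
    shape: tuple[int, int],
    pixel_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rasterize a geometry onto a pixel grid (pixel-centered sampling).

    Pixel (row, col) has its center at world coordinates
    (origin_x + (col + 0.5) * pixel_size, origin_y + (row + 0.5) * pixel_size);
    rows index y, columns index x (row-major image convention).
    """
    ny, nx = shape
    if geom is None or geom.is_empty:
        return np.zeros(shape, dtype=bool)
    xs = origin[0] + (np.arange(nx) + 0.5) * pixel_size
    ys = origin[1] + (np.arange(ny) + 0.5) * pixel_size
    # restrict the point-in-polygon test to the geometry's bounding box
    minx, miny, maxx, maxy = geom.bounds
    ci = np.nonzero((xs >= minx - pixel_size) & (xs <= maxx + pixel_size))[0]
    ri = np.nonzero((ys >= miny - pixel_size) & (ys <= maxy + pixel_size))[0]
    mask = np.zeros(shape, dtype=bool)
    if len(ci) == 0 or len(ri) == 0:
        return mask
    gx, gy = np.meshgrid(xs[ci], ys[ri])
    prepared = shapely.prepare(geom) if not shapely.is_prepared(geom) else None
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
    del prepared
    mask[np.ix_(ri, ci)] = inside
    return mask


def arc_points(
    center: np.ndarray, radius: float, start: float, stop: float, n: int = 128
) -> np.ndarray:
    """Points along a circular arc from angle start to stop (radians)."""
    t = np.linspace(start, stop, n)
    return np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )
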