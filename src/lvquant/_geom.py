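"""Internal planar-geometry helpers shared by the phantom and quantification stages.

All coordinates are physical millimetres in the short-axis plane; angles are
measured counterclockwise from the positive x-axis.
"""
from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

TWO_PI = 2.0 * np.pi


def circle_polygon(center: tuple[float, float], radius: float, n_vertices: int = 128,
                   theta0: float = 0.0) -> Polygon:
    """Regular polygon inscribed in a circle, counterclockwise."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    th = theta0 + np.arange(n_vertices) * TWO_PI / n_vertices
    pts = np.column_stack([center[0] + radius * np.cos(th),
                           center[1] + radius * np.sin(th)])
    return Polygon(pts)


def annular_wedge_polygon(center: tuple[float, float], r_inner: float, r_outer: float,
                          theta_start: float, theta_extent: float,
                          n_arc: int = 24) -> Polygon:
    """Wedge-shaped band between two radii, used for the septal ROI."""
    th = theta_start + np.linspace(0.0, theta_extent, n_arc)
    outer = np.column_stack([center[0] + r_outer * np.cos(th),
                             center[1] + r_outer * np.sin(th)])
    inner = np.column_stack([center[0] + r_inner * np.cos(th[::-1]),
                             center[1] + r_inner * np.sin(th[::-1])])
    return Polygon(np.vstack([outer, inner]))


def ensure_ccw(poly: Polygon) -> Polygon:
    return orient(poly, sign=1.0)


def polygon_vertices(poly: Polygon) -> np.ndarray:
    """Exterior vertices as an (N, 2) array without the closing duplicate."""
    xy = np.asarray(poly.exterior.coords)
    return xy[:-1]


def points_in_polygon(x: np.ndarray, y: np.ndarray, poly: Polygon) -> np.ndarray:
    """Vectorized even-odd membership test for point arrays (broadcastable)."""
    return shapely.contains_xy(poly, x, y)


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Map angles to [0, 2*pi)."""
    return np.mod(theta, TWO_PI)


def angle_in_arc(theta, arc_start: float, arc_extent: float):
    """Half-open membership theta in [arc_start, arc_start + arc_extent) mod 2*pi."""
    rel = wrap_angle(np.asarray(theta) - arc_start)
    return rel < arc_extent


def arcs_overlap(start_a: float, extent_a: float, start_b: float, extent_b: float) -> bool:
    """Whether two circular arcs [start, start+extent) intersect (mod 2*pi)."""
    rel = wrap_angle(start_b - start_a)
    return bool(rel < extent_a or rel > TWO_PI - extent_b)


def sector_arc_lengths(poly: Polygon, center: tuple[float, float],
                       reference_angle: float, n_sectors: int) -> np.ndarray:
    """Split the polygon perimeter into equal-angle sectors about ``center``.

    Each exterior edge is cut exactly where it crosses a sector-boundary ray
    (the crossing parameter is the root of a linear equation), so the returned
    lengths sum to the full perimeter to floating precision.  Assumes the
    polygon is star-shaped about ``center``, which holds for LV contours.
    """
    cx, cy = center
    verts = np.asarray(poly.exterior.coords)
    width = TWO_PI / n_sectors
    boundary_angles = reference_angle + width * np.arange(n_sectors)
    ux = np.cos(boundary_angles)
    uy = np.sin(boundary_angles)

    lengths = np.zeros(n_sectors)
    for a, b in zip(verts[:-1], verts[1:]):
        ax, ay = a[0] - cx, a[1] - cy
        dx, dy = b[0] - a[0], b[1] - a[1]
        # cross((a - c) + t*d, u) = 0  ->  t = -(ax*uy - ay*ux)/(dx*uy - dy*ux)
        denom = dx * uy - dy * ux
        numer = -(ax * uy - ay * ux)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(np.abs(denom) > 0, numer / denom, np.nan)
        # keep genuine ray crossings (forward side of the boundary ray only)
        px = ax + np.where(np.isnan(t), 0.0, t) * dx
        py = ay + np.where(np.isnan(t), 0.0, t) * dy
        fwd = px * ux + py * uy > 0
        cuts = t[np.isfinite(t) & (t > 0.0) & (t < 1.0) & fwd]
        ts = np.concatenate([[0.0], np.sort(cuts), [1.0]])
        edge_len = float(np.hypot(dx, dy))
        for t0, t1 in zip(ts[:-1], ts[1:]):
            tm = 0.5 * (t0 + t1)
            theta = np.arctan2(ay + tm * dy, ax + tm * dx)
            k = int(wrap_angle(theta - reference_angle) // width) % n_sectors
            lengths[k] += edge_len * (t1 - t0)
    return lengths


def line_polygon_intersections(point: np.ndarray, direction: np.ndarray,
                               poly: Polygon) -> np.ndarray:
    """Signed parameters t where the infinite line point + t*direction crosses
    the polygon exterior. Returned sorted ascending; may be empty."""
    verts = np.asarray(poly.exterior.coords)
    a = verts[:-1]
    d = verts[1:] - verts[:-1]
    px, py = point
    vx, vy = direction
    # solve point + t*v = a + s*d  for each edge
    denom = vx * d[:, 1] - vy * d[:, 0]
    rx = a[:, 0] - px
    ry = a[:, 1] - py
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rx * d[:, 1] - ry * d[:, 0]) / denom
        s = (rx * vy - ry * vx) / denom
    ok = np.isfinite(t) & np.isfinite(s) & (s >= 0.0) & (s < 1.0)
    return np.sort(t[ok])


def ray_boundary_distance(poly: Polygon, center: tuple[float, float],
                          angle: float) -> float:
    """Distance from ``center`` to the polygon exterior along the ray ``angle``."""
    direction = np.array([np.cos(angle), np.sin(angle)])
    ts = line_polygon_intersections(np.asarray(center, dtype=float), direction, poly)
    ts = ts[ts > 1e-12]
    if ts.size == 0:
        raise ValueError(f"ray at angle {angle:.4f} rad does not hit the polygon")
    return float(ts[0])
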