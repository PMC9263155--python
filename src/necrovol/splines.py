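"""Slice-wise concave reconstruction with closed cubic splines.

Where the ellipse backend enforces convexity, this backend draws a tight,
possibly concave hull: on each axial slice the outermost necrotic point of
every sampled half-plane direction is taken as a contour vertex, the
vertices are ordered by their cylindrical angle about the applicator axis,
and a *closed periodic cubic B-spline* is interpolated through them.  The
spline is evaluated with de Boor's recursion (numerically stable, no basis
functions formed explicitly) and densely sampled into a polygon; pixels are
classified by Sunday's winding-number test, which stays robust for points
close to complicated boundaries.  Because each vertex only influences the
four spline segments around it, a corrupted contour point perturbs the
reconstruction locally rather than globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import ApplicatorAxis, VoxelGrid, to_cylindrical

__all__ = [
    "ClosedContour",
    "contour_voxels",
    "cylindrical_order",
    "closed_spline",
    "deboor_periodic",
    "winding_number",
    "winding_inside",
    "spline_reconstruct",
]


# -- contour extraction ----------------------------------------------------


def contour_voxels(
    points: np.ndarray,
    axis: ApplicatorAxis,
    half_plane_step_deg: float,
) -> np.ndarray:
    """Outermost necrotic point per half-plane direction.

    ``points`` are in-plane (x, y) world coordinates of necrotic pixels at
    one z-level, lying on the sampled half-planes (multiples of
    ``half_plane_step_deg``).  For each direction the point of maximum
    radius is retained; these radial extremes are the contour vertex set.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        return np.empty((0, 2))
    r, theta, _ = to_cylindrical(
        np.column_stack([points, np.zeros(len(points))]), axis
    )
    n_dirs = int(round(360.0 / half_plane_step_deg))
    sector = np.round(theta / half_plane_step_deg).astype(int) % n_dirs
    out = []
    for s in np.unique(sector):
        sel = np.flatnonzero(sector == s)
        if r[sel].max() == 0.0 and len(out):
            continue  # the axis point belongs to every direction; keep once
        out.append(points[sel[np.argmax(r[sel])]])
    return np.asarray(out)


def cylindrical_order(points: np.ndarray, axis: ApplicatorAxis) -> np.ndarray:
    """Sort contour points by ascending cylindrical angle from the 0° direction.

    Ties in angle resolve by ascending radius, then by input order (stable
    sort); fewer than 3 points raise, as no closed contour exists.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 3:
        raise ValueError("need at least 3 points for a closed contour")
    r, theta, _ = to_cylindrical(
        np.column_stack([points, np.zeros(len(points))]), axis
    )
    order = np.lexsort((r, theta))
    return points[order]


# -- periodic cubic B-spline interpolation ---------------------------------


def _cyclic_control_points(vertices: np.ndarray) -> np.ndarray:
    """Solve the cyclic (1 4 1)/6 system so the B-spline interpolates the vertices."""
    n = len(vertices)
    m = np.zeros((n, n))
    idx = np.arange(n)
    m[idx, idx] = 4.0
    m[idx, (idx - 1) % n] += 1.0
    m[idx, (idx + 1) % n] += 1.0
    return np.linalg.solve(m / 6.0, vertices)


def deboor_periodic(
    control: np.ndarray, x: np.ndarray, degree: int = 3
) -> np.ndarray:
    """Evaluate a uniform periodic B-spline by de Boor's recursion.

    ``control`` are the cyclic control points d_0..d_{n-1} on the integer
    knot grid (period n); ``x`` are parameter values in knot units.  The
    recursion repeatedly forms convex combinations of the p+1 active
    control points — no basis function is ever evaluated.
    """
    control = np.asarray(control, dtype=float)
    n = len(control)
    x = np.asarray(x, dtype=float) % n
    k = np.floor(x).astype(int)  # knot span [k, k+1)
    p = degree
    # active control points for span k: indices k-p .. k (cyclic)
    d = np.stack(
        [control[(k - p + j) % n] for j in range(p + 1)], axis=0
    )  # (p+1, npts, dim)
    for r in range(1, p + 1):
        for j in range(p, r - 1, -1):
            left = k + j - p  # knot index t[j+k-p] = k+j-p (uniform knots)
            right = k + j + 1 - r
            alpha = (x - left) / (right - left)
            d[j] = (1.0 - alpha[..., None]) * d[j - 1] + alpha[..., None] * d[j]
    return d[p]


@dataclass
class ClosedContour:
    """A closed interpolating curve through ordered contour vertices.

    ``evaluate(s)`` maps s ∈ [0, 1) to a point on the curve; s = i/n hits
    vertex i exactly.  ``polygon(max_spacing)`` returns a dense polygonal
    sampling for inclusion testing.
    """

    vertices: np.ndarray
    control: np.ndarray = field(repr=False)

    def evaluate(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        n = len(self.vertices)
        # control layout: curve value at integer knot i is the interpolation
        # stencil (d[i-1] + 4 d[i] + d[i+1]) / 6, realized by an index shift
        shifted = np.roll(self.control, -2, axis=0)
        pts = deboor_periodic(shifted, np.atleast_1d(s) * n)
        return pts[0] if s.ndim == 0 else pts

    def polygon(self, max_spacing: float = 0.5) -> np.ndarray:
        """Dense open polygon tracing the closed curve once."""
        # chord-length estimate of the perimeter from the vertices
        per = np.linalg.norm(
            np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0),
            axis=1,
        ).sum()
        m = max(4 * len(self.vertices), int(np.ceil(per / max_spacing)))
        return self.evaluate(np.arange(m) / m)


def closed_spline(vertices: np.ndarray) -> ClosedContour:
    """Periodic cubic interpolating B-spline through ordered vertices.

    Coincident consecutive vertices (including the seam) are merged before
    fitting.  The curve is C², closed, and passes through every vertex.
    """
    v = np.atleast_2d(np.asarray(vertices, dtype=float))
    keep = np.ones(len(v), dtype=bool)
    for i in range(1, len(v)):
        if np.allclose(v[i], v[i - 1], atol=1e-12):
            keep[i] = False
    if len(v) > 1 and np.allclose(v[0], v[-1], atol=1e-12):
        keep[-1] = False
    v = v[keep]
    if len(v) < 3:
        raise ValueError("need at least 3 distinct vertices")
    control = _cyclic_control_points(v)
    # shift matching ClosedContour.evaluate: C(i) must equal v[i]
    return ClosedContour(vertices=v, control=control)


# -- Sunday's winding-number point-in-polygon test -------------------------


def _is_left(p0: np.ndarray, p1: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """> 0 if pts lie left of the directed line p0→p1, < 0 right, 0 on it."""
    return (p1[0] - p0[0]) * (pts[:, 1] - p0[1]) - (pts[:, 0] - p0[0]) * (
        p1[1] - p0[1]
    )


def winding_number(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Winding number of each point about a closed polygon (Sunday's form).

    Accumulates signed upward/downward edge crossings of the horizontal ray
    through each point; nonzero means inside.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polygon, dtype=float)
    wn = np.zeros(len(pts), dtype=int)
    py = pts[:, 1]
    for i in range(len(poly)):
        v0 = poly[i]
        v1 = poly[(i + 1) % len(poly)]
        left = _is_left(v0, v1, pts)
        up = (v0[1] <= py) & (v1[1] > py) & (left > 0)
        dn = (v0[1] > py) & (v1[1] <= py) & (left < 0)
        wn += up.astype(int) - dn.astype(int)
    return wn


def _on_boundary(points: np.ndarray, polygon: np.ndarray, tol: float) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polygon, dtype=float)
    hit = np.zeros(len(pts), dtype=bool)
    for i in range(len(poly)):
        a = poly[i]
        b = poly[(i + 1) % len(poly)]
        ab = b - a
        denom = ab @ ab
        if denom == 0:
            d2 = np.sum((pts - a) ** 2, axis=1)
        else:
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d2 = np.sum((pts - proj) ** 2, axis=1)
        hit |= d2 <= tol * tol
    return hit


def winding_inside(
    point,
    polygon: np.ndarray,
    include_boundary: bool = True,
    boundary_tol: float = 1e-9,
):
    """True iff the point's winding number is nonzero (or it lies on an edge).

    Accepts a single (x, y) pair or an (n, 2) array.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    inside = winding_number(pts, polygon) != 0
    if include_boundary:
        inside |= _on_boundary(pts, polygon, boundary_tol)
    if np.ndim(point) == 1:
        return bool(inside[0])
    return inside


# -- volumetric reconstruction ---------------------------------------------


def _fill_polygon(
    poly: np.ndarray,
    shape: tuple[int, int],
    spacing: tuple[float, float],
    origin: tuple[float, float],
    boundary_tol: float = 1e-9,
) -> np.ndarray:
    """Rasterize winding-number inclusion on a pixel-center grid.

    ``boundary_tol`` implements the pixel-on-boundary-is-inside convention:
    contour vertices sit exactly on the smooth curve, which the polygon
    approximates by chords lying up to one sagitta inside it, so the
    tolerance must cover that sagitta for boundary pixels to be kept.
    """
    out = np.zeros(shape, dtype=np.uint8)
    lo = poly.min(axis=0)
    hi = poly.max(axis=0)
    i0 = max(0, int(np.floor((lo[0] - origin[0]) / spacing[0])))
    i1 = min(shape[0] - 1, int(np.ceil((hi[0] - origin[0]) / spacing[0])))
    j0 = max(0, int(np.floor((lo[1] - origin[1]) / spacing[1])))
    j1 = min(shape[1] - 1, int(np.ceil((hi[1] - origin[1]) / spacing[1])))
    if i1 < i0 or j1 < j0:
        return out
    xs = origin[0] + spacing[0] * np.arange(i0, i1 + 1)
    ys = origin[1] + spacing[1] * np.arange(j0, j1 + 1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = winding_inside(pts, poly, boundary_tol=boundary_tol)
    out[i0 : i1 + 1, j0 : j1 + 1] = inside.reshape(xx.shape).astype(np.uint8)
    return out


def spline_reconstruct(
    points_by_level: dict[int, np.ndarray],
    grid: VoxelGrid,
    axis: ApplicatorAxis,
    half_plane_step_deg: float,
    polygon_spacing: float | None = None,
) -> VoxelGrid:
    """Stack per-z spline fills into a binary volume.

    ``points_by_level`` maps a grid z-index to the (n, 2) in-plane world
    coordinates of necrotic points at that level.  Levels whose contour has
    fewer than 3 vertices yield empty slices.
    """
    if polygon_spacing is None:
        polygon_spacing = 0.5 * min(grid.spacing[:2])
    out = grid.empty_like(dtype=np.uint8)
    for zi, pts in points_by_level.items():
        if zi < 0 or zi >= grid.shape[2]:
            continue
        verts = contour_voxels(pts, axis, half_plane_step_deg)
        if len(verts) < 3:
            continue
        verts = cylindrical_order(verts, axis)
        try:
            curve = closed_spline(verts)
        except ValueError:
            continue
        poly = curve.polygon(polygon_spacing)
        # worst-case chord sagitta at 1 mm curvature radius
        tol = polygon_spacing**2 / 8.0
        out.values[:, :, zi] = _fill_polygon(
            poly, grid.shape[:2], grid.spacing[:2], grid.origin[:2], tol
        )
    return out
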