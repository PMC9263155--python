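"""Convex-hull reconstruction via incremental 3D Delaunay triangulation.

The necrotic pixels of all accepted slice orientations form a 3D point
cloud; its convex hull, voxelized, is the reconstructed necrosis volume.
The hull is obtained from a Bowyer–Watson incremental Delaunay
triangulation: starting from a super-tetrahedron enclosing every point,
points are inserted one at a time — all tetrahedra whose circumsphere
contains the new point are invalid and removed, the resulting polyhedral
cavity is re-triangulated by connecting its boundary faces to the new
point, and finally every cell sharing a super-tetrahedron vertex is
discarded.  The surviving boundary faces form the convex hull.

The method produces a smooth global surface without slice-wise staircase
artifacts, but — being convex — it deliberately cannot follow concave
deformations such as heat-sink dents; that limitation is exactly what the
comparison against the spline backend quantifies.

Voxel grids are full of collinear/cospherical point configurations, so the
triangulation operates on deterministically jittered copies of the points
(seeded, ~1e-8 of the cloud extent); reported vertices remain the originals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import ApplicatorAxis, OrientedSlice, VoxelGrid, slice_to_world

__all__ = [
    "TetMesh",
    "DegenerateCloudError",
    "necrotic_point_cloud",
    "delaunay_3d",
    "hull_and_fill",
    "delaunay_reconstruct",
]


class DegenerateCloudError(ValueError):
    """Fewer than 4 points, or all points coplanar: no 3D triangulation exists."""


@dataclass
class TetMesh:
    """Tetrahedral mesh: vertices (mm), tetrahedra, and boundary (hull) faces."""

    vertices: np.ndarray
    tetrahedra: np.ndarray
    boundary_faces: np.ndarray

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices[self.tetrahedra]
        e = v[:, 1:] - v[:, :1]
        return np.abs(np.linalg.det(e)) / 6.0

    @property
    def total_volume_mm3(self) -> float:
        return float(self.tet_volumes().sum())


def _circumspheres(pts: np.ndarray, tets: np.ndarray):
    """Circumcenters and squared radii of tetrahedra (batched linear solves)."""
    v = pts[tets]  # (m, 4, 3)
    a = 2.0 * (v[:, 1:] - v[:, :1])  # (m, 3, 3)
    b = np.sum(v[:, 1:] ** 2, axis=2) - np.sum(v[:, :1] ** 2, axis=2)
    centers = np.linalg.solve(a, b[..., None])[..., 0]
    r2 = np.sum((centers - v[:, 0]) ** 2, axis=1)
    return centers, r2


class _TetStore:
    """Growable arrays of tetrahedra with an alive mask."""

    def __init__(self, cap: int = 1024):
        self.verts = np.empty((cap, 4), dtype=np.int64)
        self.centers = np.empty((cap, 3))
        self.r2 = np.empty(cap)
        self.alive = np.zeros(cap, dtype=bool)
        self.count = 0

    def add(self, verts: np.ndarray, centers: np.ndarray, r2: np.ndarray) -> None:
        m = len(verts)
        while self.count + m > len(self.alive):
            self._grow()
        sl = slice(self.count, self.count + m)
        self.verts[sl] = verts
        self.centers[sl] = centers
        self.r2[sl] = r2
        self.alive[sl] = True
        self.count += m

    def _grow(self) -> None:
        cap = 2 * len(self.alive)
        for name in ("verts", "centers", "r2", "alive"):
            arr = getattr(self, name)
            new = np.zeros((cap,) + arr.shape[1:], dtype=arr.dtype)
            new[: len(arr)] = arr
            setattr(self, name, new)


def delaunay_3d(
    points: np.ndarray, jitter: float = 1e-8, seed: int = 0
) -> TetMesh:
    """Bowyer–Watson incremental Delaunay triangulation of a 3D point cloud.

    Every returned tetrahedron satisfies the empty-circumsphere property
    (up to the jitter scale); the boundary faces of the union of cells form
    the convex hull of the input.  Raises :class:`DegenerateCloudError` for
    < 4 distinct points or a coplanar cloud — callers should fall back to
    2D handling in that case.
    """
    pts = np.unique(np.atleast_2d(np.asarray(points, dtype=float)), axis=0)
    n = len(pts)
    if n < 4:
        raise DegenerateCloudError(f"need at least 4 distinct points, got {n}")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 3:
        raise DegenerateCloudError("points are coplanar")

    scale = max(np.ptp(pts, axis=0).max(), 1.0)
    rng = np.random.default_rng(seed)
    work = pts + rng.uniform(-jitter, jitter, pts.shape) * scale

    # super-tetrahedron far outside the cloud
    center = work.mean(axis=0)
    big = 1e3 * scale
    sup = center + big * np.array(
        [
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]
    )
    allpts = np.vstack([work, sup])
    store = _TetStore()
    first = np.array([[n, n + 1, n + 2, n + 3]], dtype=np.int64)
    c0, r0 = _circumspheres(allpts, first)
    store.add(first, c0, r0)

    for pi in range(n):
        p = allpts[pi]
        live = np.flatnonzero(store.alive[: store.count])
        d2 = np.sum((store.centers[live] - p) ** 2, axis=1)
        bad = live[d2 < store.r2[live]]
        if len(bad) == 0:  # numerically outside everything: should not happen
            raise RuntimeError("point fell outside the triangulation")
        # cavity boundary: faces of bad tets appearing exactly once
        faces: dict[tuple, int] = {}
        for t in store.verts[bad]:
            for f in (
                (t[0], t[1], t[2]),
                (t[0], t[1], t[3]),
                (t[0], t[2], t[3]),
                (t[1], t[2], t[3]),
            ):
                key = tuple(sorted(f))
                faces[key] = faces.get(key, 0) + 1
        store.alive[bad] = False
        boundary = [f for f, cnt in faces.items() if cnt == 1]
        new = np.array(
            [[f[0], f[1], f[2], pi] for f in boundary], dtype=np.int64
        )
        centers, r2 = _circumspheres(allpts, new)
        store.add(new, centers, r2)

    keep = store.verts[: store.count][store.alive[: store.count]]
    real = keep[(keep < n).all(axis=1)]
    if len(real) == 0:
        raise DegenerateCloudError("no real tetrahedra survived")
    # boundary faces = faces belonging to exactly one tetrahedron
    fc: dict[tuple, int] = {}
    for t in real:
        for f in (
            (t[0], t[1], t[2]),
            (t[0], t[1], t[3]),
            (t[0], t[2], t[3]),
            (t[1], t[2], t[3]),
        ):
            key = tuple(sorted(f))
            fc[key] = fc.get(key, 0) + 1
    bfaces = np.array([f for f, cnt in fc.items() if cnt == 1], dtype=np.int64)
    return TetMesh(vertices=pts, tetrahedra=real, boundary_faces=bfaces)


def _hull_planes(mesh: TetMesh):
    """Outward unit normals and offsets of the hull faces."""
    tri = mesh.vertices[mesh.boundary_faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > 1e-12
    normals, tri = normals[ok] / norms[ok, None], tri[ok]
    inner = mesh.vertices.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, inner - tri[:, 0]) > 0
    normals[flip] *= -1.0
    offsets = np.einsum("ij,ij->i", normals, tri[:, 0])
    return normals, offsets


def hull_and_fill(
    mesh: TetMesh, grid: VoxelGrid, tol: float = 1e-7
) -> VoxelGrid:
    """Mark every voxel whose center lies inside or on the convex hull.

    Half-space test against the hull's face planes, restricted to the hull
    bounding box and chunked per z-slab.
    """
    normals, offsets = _hull_planes(mesh)
    out = grid.empty_like(dtype=np.uint8)
    xs, ys, zs = grid.axis_coords()
    lo = mesh.vertices.min(axis=0) - tol
    hi = mesh.vertices.max(axis=0) + tol
    isel = np.flatnonzero((xs >= lo[0]) & (xs <= hi[0]))
    jsel = np.flatnonzero((ys >= lo[1]) & (ys <= hi[1]))
    ksel = np.flatnonzero((zs >= lo[2]) & (zs <= hi[2]))
    if not (len(isel) and len(jsel) and len(ksel)):
        return out
    xx, yy = np.meshgrid(xs[isel], ys[jsel], indexing="ij")
    for k in ksel:
        pts = np.column_stack(
            [xx.ravel(), yy.ravel(), np.full(xx.size, zs[k])]
        )
        inside = np.all(pts @ normals.T <= offsets + tol, axis=1)
        out.values[np.ix_(isel, jsel, [k])] = inside.reshape(
            len(isel), len(jsel), 1
        ).astype(np.uint8)
    return out


def necrotic_point_cloud(
    masks: list[OrientedSlice],
    axis: ApplicatorAxis,
    contour_only: bool = True,
) -> np.ndarray:
    """World coordinates of necrotic pixels across all accepted orientations.

    Duplicate points on the shared axis column are deduplicated.  With
    ``contour_only`` each mask is reduced to its morphological boundary
    pixels — an exact optimization for convex-hull purposes, since interior
    points can never be hull vertices.
    """
    clouds = []
    for sl in masks:
        m = np.asarray(sl.pixels).astype(bool)
        if contour_only and m.any():
            m = m & ~ndimage.binary_erosion(m)
        idx = np.argwhere(m)
        if len(idx) == 0:
            continue
        clouds.append(slice_to_world(sl, idx, axis))
    if not clouds:
        return np.empty((0, 3))
    pts = np.vstack(clouds)
    return np.unique(np.round(pts, 6), axis=0)


def delaunay_reconstruct(
    masks: list[OrientedSlice],
    grid: VoxelGrid,
    axis: ApplicatorAxis,
    seed: int = 0,
) -> VoxelGrid:
    """Point cloud → Delaunay hull → voxel fill; empty volume if degenerate."""
    cloud = necrotic_point_cloud(masks, axis)
    try:
        mesh = delaunay_3d(cloud, seed=seed)
    except DegenerateCloudError:
        return grid.empty_like(dtype=np.uint8)
    return hull_and_fill(mesh, grid)
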