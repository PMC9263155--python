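"""Slice-wise minimum-area enclosing ellipses.

An ablation applicator acts as a line of heat point sources, so in
homogeneous tissue the coagulation zone is ideally an ellipsoid centered on
the applicator axis.  This backend exploits that prior: on every axial
slice (perpendicular to the axis) it fits the minimum-area ellipse enclosing
the necrotic points gathered from all accepted slice orientations, and marks
every pixel inside the ellipse as coagulated.  Stacked over z this yields a
convex-per-slice 3D necrosis volume that bridges gaps from incomplete or
noisy data — at the price of also bridging true concavities such as
heat-sink dents.

The fit is Khachiyan's first-order algorithm: lift the d-dimensional points
to d+1 dimensions, iterate the dual weights u (a probability vector over the
points) by

    u ← (1−β) u + β e_j,   β = (M_j − d − 1) / ((d + 1)(M_j − 1)),

where M_j is the largest Mahalanobis-type statistic q_jᵀ X(u)⁻¹ q_j, until
max_j M_j ≤ (d+1)(1+ε).  The ellipse shape matrix is then

    A = (1/d) · (Σ u_i P_i P_iᵀ − c cᵀ)⁻¹,   c = Σ u_i P_i,

and points on the boundary satisfy (p−c)ᵀ A (p−c) = 1.  After convergence A
is rescaled (if needed) by the maximum quadratic form over the inputs so
enclosure is exact, not just ε-approximate.  Radii and orientation come from
the symmetric eigendecomposition of A: r_i = 1/√λ_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ApplicatorAxis, VoxelGrid

__all__ = ["Ellipse2D", "DegenerateInputError", "mvee_fit", "fill_ellipse", "mvee_reconstruct"]


class DegenerateInputError(ValueError):
    """Point set too degenerate for an ellipse (fewer than 3 points, or collinear)."""


@dataclass
class Ellipse2D:
    """An ellipse: center c, semi-axes r1 ≥ r2, rotation basis, shape matrix A.

    Boundary points satisfy (p − c)ᵀ A (p − c) = 1; the columns of
    ``rotation`` are the unit axis directions, and A = R diag(1/r²) Rᵀ.
    """

    center: np.ndarray
    radii: np.ndarray
    rotation: np.ndarray
    shape_matrix: np.ndarray

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.radii[0] * self.radii[1])

    def quadratic_form(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", d, self.shape_matrix, d)

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        return self.quadratic_form(points) <= 1.0 + tol

    @classmethod
    def from_parameters(
        cls, center, radii, rotation: np.ndarray
    ) -> "Ellipse2D":
        """Rebuild the shape matrix from center, radii and rotation basis."""
        radii = np.asarray(radii, dtype=float)
        rotation = np.asarray(rotation, dtype=float)
        a = rotation @ np.diag(1.0 / radii**2) @ rotation.T
        return cls(np.asarray(center, dtype=float), radii, rotation, a)


def _decompose(center: np.ndarray, a: np.ndarray) -> Ellipse2D:
    # symmetric eigendecomposition; eigenvalues ascending => radii descending
    w, v = np.linalg.eigh(a)
    radii = 1.0 / np.sqrt(w)
    order = np.argsort(radii)[::-1]
    return Ellipse2D(center, radii[order], v[:, order], a)


def mvee_fit(
    points: np.ndarray, tolerance: float = 1e-4, max_iter: int = 1000
) -> Ellipse2D:
    """Minimum-area enclosing ellipse of 2D points (Khachiyan iteration).

    Deterministic; raises :class:`DegenerateInputError` for < 3 points or a
    collinear set (a point or segment has no enclosing ellipse of finite
    eccentricity).  All input points satisfy quadratic form ≤ 1 exactly on
    return.
    """
    p = np.unique(np.atleast_2d(np.asarray(points, dtype=float)), axis=0)
    n, d = p.shape
    if d != 2:
        raise ValueError("mvee_fit expects 2D points")
    if n < 3:
        raise DegenerateInputError(f"need at least 3 distinct points, got {n}")
    if np.linalg.matrix_rank(p - p.mean(axis=0), tol=1e-9) < 2:
        raise DegenerateInputError("points are collinear")

    q = np.column_stack([p, np.ones(n)]).T  # (d+1, n) lifted points
    u = np.full(n, 1.0 / n)
    dim = d + 1
    for _ in range(max_iter):
        x = q @ (u[:, None] * q.T)  # (d+1, d+1)
        try:
            xq = np.linalg.solve(x, q)
        except np.linalg.LinAlgError:
            xq = np.linalg.pinv(x) @ q  # near-degenerate weights
        m = np.einsum("ij,ji->i", q.T, xq)
        j = int(np.argmax(m))
        mj = m[j]
        if mj <= dim * (1.0 + tolerance):
            break
        beta = (mj - dim) / (dim * (mj - 1.0))
        u *= 1.0 - beta
        u[j] += beta

    c = p.T @ u
    cov = (p.T * u) @ p - np.outer(c, c)
    try:
        a = np.linalg.inv(cov) / d
    except np.linalg.LinAlgError:
        raise DegenerateInputError("point set numerically collinear")
    if not np.all(np.isfinite(a)) or np.linalg.eigvalsh(a).min() <= 0:
        raise DegenerateInputError("point set numerically collinear")
    # make enclosure exact: scale by the worst quadratic form if it exceeds 1
    dp = p - c
    qf = np.einsum("ij,jk,ik->i", dp, a, dp)
    worst = qf.max()
    if worst > 1.0:
        a = a / worst
    return _decompose(c, a)


def fill_ellipse(
    e: Ellipse2D,
    shape: tuple[int, int],
    spacing: tuple[float, float] = (1.0, 1.0),
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rasterize an ellipse: pixel marked iff its center satisfies QF ≤ 1 (inclusive)."""
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    d0 = xx - e.center[0]
    d1 = yy - e.center[1]
    a = e.shape_matrix
    qf = a[0, 0] * d0 * d0 + 2.0 * a[0, 1] * d0 * d1 + a[1, 1] * d1 * d1
    return qf <= 1.0


def mvee_reconstruct(
    points_by_level: dict[int, np.ndarray],
    grid: VoxelGrid,
    tolerance: float = 1e-4,
) -> VoxelGrid:
    """Stack per-z minimum-area ellipses into a binary volume.

    ``points_by_level`` maps a grid z-index to the (n, 2) in-plane world
    coordinates of necrotic points at that level (gathered from all accepted
    orientations).  Levels with fewer than 3 points, or collinear points
    (e.g. a single remaining orientation), yield empty slices.
    """
    out = grid.empty_like(dtype=np.uint8)
    for zi, pts in points_by_level.items():
        if zi < 0 or zi >= grid.shape[2]:
            continue
        pts = np.atleast_2d(pts)
        if len(pts) < 3:
            continue
        try:
            e = mvee_fit(pts, tolerance=tolerance)
        except DegenerateInputError:
            continue
        out.values[:, :, zi] = fill_ellipse(
            e,
            grid.shape[:2],
            grid.spacing[:2],
            grid.origin[:2],
        ).astype(np.uint8)
    return out
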