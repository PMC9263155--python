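"""Coordinate conventions for rotated-slice thermometry.

All reconstruction backends share one geometry: a set of 2D imaging planes
rotated about the ablation applicator's main axis, which is parallel to the
z-axis of an axis-aligned voxel grid.  World coordinates are in millimetres,
right-handed; voxel indices are 0-based and a voxel's world position is the
position of its *center* (NIfTI convention).

A single acquired slice contains the applicator axis, so it covers **two**
half-planes: the one at its nominal angle θ (pixels with positive signed
in-plane offset ``u``) and the opposite one at θ+180° (negative ``u``).  A
series of 8 slices therefore samples 16 half-plane directions spaced 22.5°
apart — the angular grid all slice-wise reconstructions operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "ApplicatorAxis",
    "OrientedSlice",
    "OrientedSliceSeries",
    "CylindricalCoord",
    "slice_to_world",
    "world_to_slice",
    "to_cylindrical",
    "half_plane_angles",
    "resample_slices_to_grid",
]


@dataclass
class VoxelGrid:
    """A 3D scalar or binary field on a regular, axis-aligned grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar field (°C, binary mask, ...).
    spacing : triple of float
        Voxel edge lengths in mm; strictly positive.
    origin : triple of float
        World position (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelGrid values must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.values), (0, 1)).all())

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )  # type: ignore[return-value]

    def empty_like(self, dtype=float, fill=0) -> "VoxelGrid":
        return VoxelGrid(
            np.full(self.shape, fill, dtype=dtype), self.spacing, self.origin
        )

    def copy(self) -> "VoxelGrid":
        return replace(self, values=self.values.copy())


@dataclass(frozen=True)
class ApplicatorAxis:
    """The applicator's main axis: a line parallel to the grid z-axis.

    ``center_xy`` is the (x_c, y_c) world position (mm) where the axis
    pierces every axial plane.
    """

    center_xy: tuple[float, float] = (0.0, 0.0)

    @property
    def x(self) -> float:
        return self.center_xy[0]

    @property
    def y(self) -> float:
        return self.center_xy[1]


@dataclass(frozen=True)
class CylindricalCoord:
    """Cylinder coordinates about the applicator axis: r in mm, θ in [0, 360) degrees."""

    r: float
    theta_deg: float
    z: float


@dataclass
class OrientedSlice:
    """One 2D image plane containing the applicator axis.

    ``pixels`` is indexed ``[i, j]`` where ``i`` runs across the axis
    (signed in-plane offset ``u = (i - u0) * du`` mm) and ``j`` runs along
    the axis (``z = z0 + j * dv`` mm).  ``angle_deg`` is the plane's
    rotation about the axis, in [0, 180).
    """

    angle_deg: float
    pixels: np.ndarray
    in_plane_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 5.0
    timestamp: float = 0.0
    u0: float | None = None  # pixel row index lying on the axis
    z0: float = 0.0  # world z of pixel column j=0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2D")
        if self.u0 is None:
            self.u0 = self.pixels.shape[0] // 2
        self.in_plane_spacing = tuple(float(s) for s in self.in_plane_spacing)
        if any(s <= 0 for s in self.in_plane_spacing):
            raise ValueError("in-plane spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def u_mm(self, i) -> np.ndarray:
        """Signed in-plane offset (mm) of pixel row(s) ``i`` from the axis."""
        return (np.asarray(i, dtype=float) - self.u0) * self.in_plane_spacing[0]

    def z_mm(self, j) -> np.ndarray:
        return self.z0 + np.asarray(j, dtype=float) * self.in_plane_spacing[1]


class OrientedSliceSeries:
    """A collection of :class:`OrientedSlice` grouped by angle and timestamp.

    Angles must be uniformly spaced: consecutive difference 180/n_orientations
    degrees, so the series samples the cylinder at 2·n_orientations half-planes.
    """

    def __init__(self, slices: Iterable[OrientedSlice]):
        self.slices: list[OrientedSlice] = sorted(
            slices, key=lambda s: (s.timestamp, s.angle_deg)
        )
        angles = self.angles
        if len(angles) > 1:
            step = 180.0 / len(angles)
            diffs = np.diff(angles)
            if not np.allclose(diffs, step, atol=1e-9):
                raise ValueError(
                    f"orientation angles {angles} are not uniformly spaced by {step}"
                )
        seen = set()
        for s in self.slices:
            key = (round(s.angle_deg, 9), round(s.timestamp, 9))
            if key in seen:
                raise ValueError(f"duplicate slice at angle/time {key}")
            seen.add(key)

    @property
    def angles(self) -> list[float]:
        return sorted({s.angle_deg for s in self.slices})

    @property
    def n_orientations(self) -> int:
        return len(self.angles)

    @property
    def timestamps(self) -> list[float]:
        return sorted({s.timestamp for s in self.slices})

    def at_time(self, t: float) -> "OrientedSliceSeries":
        sub = [s for s in self.slices if np.isclose(s.timestamp, t)]
        return OrientedSliceSeries(sub)

    def orientation(self, angle_deg: float) -> list[OrientedSlice]:
        """All slices at one orientation, time-ordered."""
        return sorted(
            (s for s in self.slices if np.isclose(s.angle_deg, angle_deg)),
            key=lambda s: s.timestamp,
        )

    def get(self, angle_deg: float, t: float) -> OrientedSlice:
        for s in self.slices:
            if np.isclose(s.angle_deg, angle_deg) and np.isclose(s.timestamp, t):
                return s
        raise KeyError((angle_deg, t))

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)


def half_plane_angles(n_orientations: int) -> np.ndarray:
    """The 2·n half-plane sampling directions (degrees in [0, 360))."""
    return np.arange(2 * n_orientations) * (180.0 / n_orientations)


def slice_to_world(
    sl: OrientedSlice, pixel, axis: ApplicatorAxis
) -> np.ndarray:
    """Map slice pixel indices to world mm.

    ``pixel`` is an (i, j) pair or an (n, 2) array of pairs.  Returns the
    world position(s): axis + u·(cos θ, sin θ, 0) + (0, 0, z).
    """
    px = np.atleast_2d(np.asarray(pixel, dtype=float))
    ni, nj = sl.shape
    if (px[:, 0] < 0).any() or (px[:, 0] > ni - 1).any() or (
        px[:, 1] < 0
    ).any() or (px[:, 1] > nj - 1).any():
        raise IndexError("pixel index outside slice bounds")
    u = sl.u_mm(px[:, 0])
    z = sl.z_mm(px[:, 1])
    th = np.deg2rad(sl.angle_deg)
    out = np.column_stack(
        [axis.x + u * np.cos(th), axis.y + u * np.sin(th), z]
    )
    return out[0] if np.ndim(pixel) == 1 else out


def world_to_slice(
    sl: OrientedSlice, point, axis: ApplicatorAxis, atol: float = 1e-6
) -> np.ndarray:
    """Inverse of :func:`slice_to_world` for points on the slice plane."""
    p = np.atleast_2d(np.asarray(point, dtype=float))
    th = np.deg2rad(sl.angle_deg)
    d = np.array([np.cos(th), np.sin(th)])
    rel = p[:, :2] - np.array([axis.x, axis.y])
    u = rel @ d
    off_plane = rel - np.outer(u, d)
    if (np.linalg.norm(off_plane, axis=1) > atol).any():
        raise ValueError("point does not lie on the slice plane")
    i = u / sl.in_plane_spacing[0] + sl.u0
    j = (p[:, 2] - sl.z0) / sl.in_plane_spacing[1]
    out = np.column_stack([i, j])
    return out[0] if np.ndim(point) == 1 else out


def to_cylindrical(point, axis: ApplicatorAxis):
    """Cylinder coordinates of world point(s) about the applicator axis.

    θ is the standard two-argument arctangent of (y−y_c, x−x_c) mapped to
    [0, 360); a point exactly on the axis gets r = 0, θ = 0 by convention.
    Accepts one point (returns :class:`CylindricalCoord`) or an (n, 3)
    array (returns (r, θ_deg, z) arrays).
    """
    p = np.atleast_2d(np.asarray(point, dtype=float))
    dx = p[:, 0] - axis.x
    dy = p[:, 1] - axis.y
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    theta = np.where(r == 0, 0.0, theta)
    if np.ndim(point) == 1:
        return CylindricalCoord(float(r[0]), float(theta[0]), float(p[0, 2]))
    return r, theta, p[:, 2]


def resample_slices_to_grid(
    series: OrientedSliceSeries, grid: VoxelGrid, axis: ApplicatorAxis
) -> tuple[VoxelGrid, VoxelGrid]:
    """Scatter slice pixels into the nearest grid voxels (nearest neighbor).

    The series must cover a single timestamp.  Returns ``(values, populated)``
    where ``populated`` is a binary grid marking voxels intersected by at
    least one slice plane; all other voxels of ``values`` are 0 and "absent".
    """
    if len(series.timestamps) > 1:
        raise ValueError("series must cover a single timestamp")
    vals = np.zeros(grid.shape, dtype=float)
    pop = np.zeros(grid.shape, dtype=np.uint8)
    for sl in series:
        if not np.isclose(sl.in_plane_spacing[1], grid.spacing[2]):
            raise ValueError(
                "slice z spacing does not match grid z spacing"
            )
        ii, jj = np.meshgrid(
            np.arange(sl.shape[0]), np.arange(sl.shape[1]), indexing="ij"
        )
        pts = slice_to_world(
            sl, np.column_stack([ii.ravel(), jj.ravel()]), axis
        )
        idx = np.round(
            (pts - np.asarray(grid.origin)) / np.asarray(grid.spacing)
        ).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        idx = idx[ok]
        vals[idx[:, 0], idx[:, 1], idx[:, 2]] = sl.pixels.ravel()[ok]
        pop[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return (
        VoxelGrid(vals, grid.spacing, grid.origin),
        VoxelGrid(pop, grid.spacing, grid.origin),
    )
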