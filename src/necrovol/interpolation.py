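"""Baseline method: volumetric heat-map reconstruction by angular interpolation.

Unlike the three shape-fitting backends, this method reconstructs the
*temperature field* itself and thresholds it afterwards.  Every voxel is
assigned the convex combination of the temperatures of its two adjacent
half-plane partners:

    T_i = I_w · (w_left · T_left + w_right · T_right),

where the weights are the complementary normalized angular distances to the
bracketing planes (the nearer plane gets the larger weight, so the field is
continuous across acquired planes) and I_w is a binary indicator of the
region-of-interest cylinder around the applicator.  The weights depend only
on geometry, so a *population map* is computed once after the reference
acquisition and reused for every incoming timepoint.

Because the necrosis estimate comes from thresholding the fused volume,
per-orientation ("local") thresholds cannot be applied to this method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .geometry import (
    ApplicatorAxis,
    OrientedSlice,
    VoxelGrid,
    half_plane_angles,
)

__all__ = [
    "PopulationMap",
    "UnsupportedPolicyError",
    "build_population_map",
    "half_plane_profiles",
    "interpolate_volume",
    "interp_reconstruct",
]


class UnsupportedPolicyError(ValueError):
    """Raised for threshold policies the interpolation method cannot honor."""


@dataclass
class PopulationMap:
    """Per-voxel interpolation geometry, independent of temperature data.

    All arrays are (nx, ny): the geometry is constant along z because the
    applicator axis is parallel to z.
    """

    angles_deg: np.ndarray
    r_mm: np.ndarray
    theta_deg: np.ndarray
    left: np.ndarray
    right: np.ndarray
    w_left: np.ndarray
    w_right: np.ndarray
    inside_roi: np.ndarray


def build_population_map(
    grid: VoxelGrid,
    axis: ApplicatorAxis,
    angles_deg: np.ndarray | None = None,
    n_orientations: int = 8,
    roi_radius_mm: float = 30.0,
) -> PopulationMap:
    """Bracket every voxel's azimuth between its two nearest half-planes.

    Angular distances are taken on the shortest wrapped arc (including
    across 360°→0°); a voxel lying exactly on a half-plane gives that plane
    the full weight.  ``inside_roi`` marks voxels within the ROI cylinder.
    """
    if angles_deg is None:
        angles_deg = half_plane_angles(n_orientations)
    angles = np.sort(np.asarray(angles_deg, dtype=float) % 360.0)
    if len(angles) < 2:
        raise ValueError("need at least 2 half-plane angles")
    xs, ys, _ = grid.axis_coords()
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    dx = xx - axis.x
    dy = yy - axis.y
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    theta = np.where(r == 0, 0.0, theta)

    # left partner: largest sampled angle <= theta (wrapping below the first)
    li = np.searchsorted(angles, theta, side="right") - 1
    wrapped = li < 0
    li = np.where(wrapped, len(angles) - 1, li)
    ri = (li + 1) % len(angles)
    left_ang = angles[li]
    right_ang = angles[ri]
    gap = np.mod(right_ang - left_ang, 360.0)
    gap = np.where(gap == 0, 360.0, gap)
    dl = np.mod(theta - left_ang, 360.0)
    w_left = 1.0 - dl / gap
    w_right = 1.0 - w_left
    return PopulationMap(
        angles_deg=angles,
        r_mm=r,
        theta_deg=theta,
        left=li,
        right=ri,
        w_left=w_left,
        w_right=w_right,
        inside_roi=r <= roi_radius_mm,
    )


def half_plane_profiles(
    slices: list[OrientedSlice], angles_deg: np.ndarray
) -> tuple[np.ndarray, float]:
    """Split each acquired slice into its two half-plane radial profiles.

    Returns ``(profiles, dr)`` with ``profiles[h, ir, iz]`` the temperature
    at radius ir·dr on half-plane h (ordered like ``angles_deg``); missing
    half-planes are NaN-filled and handled downstream.
    """
    angles = np.asarray(angles_deg, dtype=float) % 360.0
    by_angle = {s.angle_deg % 360.0: s for s in slices}
    some = next(iter(by_angle.values()))
    dr = some.in_plane_spacing[0]
    u0 = int(round(some.u0))
    nu, nz = some.shape
    nr = min(u0 + 1, nu - u0)
    profiles = np.full((len(angles), nr, nz), np.nan)
    for h, ang in enumerate(angles):
        plane = ang % 180.0
        sl = by_angle.get(plane)
        if sl is None:
            continue
        u0s = int(round(sl.u0))
        if ang < 180.0:  # positive-u side
            profiles[h] = sl.pixels[u0s : u0s + nr, :]
        else:  # negative-u side, radius grows toward smaller i
            profiles[h] = sl.pixels[u0s - nr + 1 : u0s + 1, :][::-1, :]
    return profiles, dr


def interpolate_volume(
    pmap: PopulationMap,
    profiles: np.ndarray,
    dr: float,
    baseline_temp_c: float = 20.0,
) -> VoxelGrid | np.ndarray:
    """Blend partner half-plane temperatures into a full 3D field (°C).

    Each voxel samples both partners at its (r, z) by nearest neighbor
    along the half-plane and mixes them with the population-map weights.
    Voxels outside the ROI — or with both partners missing — fall back to
    the baseline temperature.
    """
    n_half, nr, nz = profiles.shape
    ir = np.clip(np.round(pmap.r_mm / dr).astype(int), 0, nr - 1)
    t_left = profiles[pmap.left, ir, :]  # (nx, ny, nz)
    t_right = profiles[pmap.right, ir, :]
    wl = pmap.w_left[..., None]
    wr = pmap.w_right[..., None]
    temp = wl * t_left + wr * t_right
    # single-sided fallback when one partner is missing
    only_left = np.isnan(t_right) & ~np.isnan(t_left)
    only_right = np.isnan(t_left) & ~np.isnan(t_right)
    temp = np.where(only_left, t_left, temp)
    temp = np.where(only_right, t_right, temp)
    temp = np.where(np.isnan(temp), baseline_temp_c, temp)
    temp = np.where(pmap.inside_roi[..., None], temp, baseline_temp_c)
    return temp


def interp_reconstruct(
    slices: list[OrientedSlice],
    tau_c: float,
    grid: VoxelGrid,
    axis: ApplicatorAxis,
    roi_radius_mm: float = 30.0,
    baseline_temp_c: float = 20.0,
    pmap: PopulationMap | None = None,
) -> VoxelGrid:
    """Interpolated heat map → 3D threshold at τ → 3D largest component."""
    angles_acquired = sorted({s.angle_deg for s in slices})
    angles = half_plane_angles(len(angles_acquired))
    if pmap is None:
        pmap = build_population_map(
            grid, axis, angles, roi_radius_mm=roi_radius_mm
        )
    profiles, dr = half_plane_profiles(slices, angles)
    temp = interpolate_volume(pmap, profiles, dr, baseline_temp_c)
    mask = temp >= tau_c
    out = grid.empty_like(dtype=np.uint8)
    if mask.any():
        labels = measure.label(mask, connectivity=3)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out.values[:] = (labels == sizes.argmax()).astype(np.uint8)
    return out
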