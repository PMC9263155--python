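"""Synthetic bio-protein-phantom experiments.

Emulates a microwave-ablation monitoring experiment: an ellipsoidal
coagulation-necrosis zone centered on the applicator grows monotonically
over a ~15 minute ablation, imaged as 8 slice orientations rotated in
22.5° steps about the applicator axis (256×256 px at 1.0×1.0 mm in-plane,
5 mm thickness).  The emulation covers the features that exercise the
reconstruction algorithms:

* per-orientation coagulation-threshold inhomogeneity in the 50–60 °C
  range (bio-protein phantoms coagulate at a pH-dependent temperature);
* an optional heat-sink vessel — a 5 mm tube with 1 mm wall parallel to
  the applicator — that dents the necrosis zone concavely;
* additive Gaussian temperature noise (±1 °C default) plus stronger
  background noise outside the 60×60 mm region of interest;
* scheduled low-SNR "outlier" slices whose thresholded area inflates by
  far more than 80% versus the previous timepoint.

The temperature model is a Gaussian profile in the scaled elliptic radius,
*not* a bioheat solution: the reconstruction algorithms only consume
thresholded masks, so only the level sets need to be realistic.  The model
is built so that, at zero noise, thresholding the field at the (sector-wise)
coagulation threshold reproduces the analytic ground-truth mask exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import (
    ApplicatorAxis,
    OrientedSlice,
    OrientedSliceSeries,
    VoxelGrid,
)

__all__ = [
    "VesselSpec",
    "PhantomSpec",
    "generate_ground_truth",
    "simulate_temperature_field",
    "sample_slice_series",
    "reslice_ground_truth",
    "analytic_ellipsoid_volume_mm3",
]


@dataclass(frozen=True)
class VesselSpec:
    """A straight heat-sink tube (5 mm diameter, 1 mm wall by default).

    The tube center line passes through the point offset by ``offset_xy``
    (mm, relative to the applicator axis) at height ``z_frac`` (fraction of
    the grid z-extent) and runs along ``direction`` — ``(0, 0, 1)`` for a
    tube parallel to the applicator, ``(1, 0, 0)`` for one crossing it
    perpendicularly, as tubes are typically inserted into a phantom.
    ``cooling_mm`` is how far beyond the outer wall the tissue stays below
    the coagulation threshold.
    """

    offset_xy: tuple[float, float] = (9.0, 0.0)
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    z_frac: float = 0.5
    diameter_mm: float = 5.0
    wall_mm: float = 1.0
    cooling_mm: float = 0.5

    @property
    def outer_radius_mm(self) -> float:
        return self.diameter_mm / 2.0 + self.wall_mm

    @property
    def cooling_radius_mm(self) -> float:
        return self.outer_radius_mm + self.cooling_mm


@dataclass
class PhantomSpec:
    """Full description of one synthetic phantom experiment.

    Defaults follow the emulated acquisition: 8 orientations of 256×256 px
    slices at 1×1 mm in-plane spacing, a 900 s ablation, thresholds drawn
    per orientation from [50, 60] °C, room-temperature (20 °C) baseline.
    """

    grid_shape: tuple[int, int, int] = (256, 256, 256)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_orientations: int = 8
    #: necrosis semi-axes (mm) reached at ``duration_s``
    final_semi_axes: tuple[float, float, float] = (14.0, 14.0, 22.0)
    duration_s: float = 900.0
    #: per-orientation coagulation thresholds (°C); scalar = homogeneous,
    #: None = drawn uniformly from threshold_range with the spec's seed
    thresholds: float | Sequence[float] | None = None
    threshold_range: tuple[float, float] = (50.0, 60.0)
    vessel: VesselSpec | None = None
    noise_sd: float = 1.0
    background_noise_sd: float = 8.0
    roi_size_mm: float = 60.0
    #: (orientation angle deg, timestamp s) pairs to corrupt
    outlier_schedule: frozenset = frozenset()
    outlier_noise_sd: float = 50.0
    baseline_temp_c: float = 20.0
    peak_temp_c: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_orientations < 2:
            raise ValueError("need at least 2 orientations")
        self.outlier_schedule = frozenset(
            (float(a), float(t)) for a, t in self.outlier_schedule
        )
        lo, hi = self.threshold_range
        taus = self.orientation_thresholds()
        if (taus < lo - 1e-9).any() or (taus > hi + 1e-9).any():
            raise ValueError(f"thresholds must lie within {self.threshold_range}")
        if min(self.final_semi_axes) <= 0:
            raise ValueError("final semi-axes must be positive")

    # -- derived geometry -------------------------------------------------
    @property
    def axis(self) -> ApplicatorAxis:
        cx = self.spacing[0] * (self.grid_shape[0] // 2)
        cy = self.spacing[1] * (self.grid_shape[1] // 2)
        return ApplicatorAxis((cx, cy))

    @property
    def center(self) -> np.ndarray:
        """World center of the necrosis ellipsoid (on the axis, mid-z)."""
        cz = self.spacing[2] * (self.grid_shape[2] // 2)
        return np.array([self.axis.x, self.axis.y, cz])

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_orientations) * (180.0 / self.n_orientations)

    def make_grid(self, dtype=float) -> VoxelGrid:
        return VoxelGrid(np.zeros(self.grid_shape, dtype=dtype), self.spacing)

    def orientation_thresholds(self) -> np.ndarray:
        """One coagulation threshold (°C) per orientation."""
        if self.thresholds is None:
            rng = np.random.default_rng([int(self.seed) % (2**31), 7919])
            lo, hi = self.threshold_range
            return rng.uniform(lo, hi, self.n_orientations)
        if np.isscalar(self.thresholds):
            return np.full(self.n_orientations, float(self.thresholds))
        taus = np.asarray(self.thresholds, dtype=float)
        if taus.shape != (self.n_orientations,):
            raise ValueError("need one threshold per orientation")
        return taus

    def semi_axes_at(self, t: float) -> np.ndarray:
        """Necrosis semi-axes at time t: √(t/duration) growth, monotone."""
        if t < 0 or t > self.duration_s + 1e-9:
            raise ValueError("t outside the simulated duration")
        frac = np.sqrt(t / self.duration_s)
        return frac * np.asarray(self.final_semi_axes)


# -- field evaluation ------------------------------------------------------


def _sector_thresholds_at(spec: PhantomSpec, theta_deg: np.ndarray) -> np.ndarray:
    """Coagulation threshold at azimuth θ: nearest-orientation sector, 180°-periodic.

    Both half-planes of one acquired slice share the same threshold, so the
    per-orientation optimum search on either half recovers the same value.
    """
    taus = spec.orientation_thresholds()
    step = 180.0 / spec.n_orientations
    sector = np.round(np.mod(theta_deg, 180.0) / step).astype(int) % spec.n_orientations
    return taus[sector]


def vessel_line(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Anchor point and unit direction of the vessel center line (world mm)."""
    v = spec.vessel
    anchor = np.array(
        [
            spec.axis.x + v.offset_xy[0],
            spec.axis.y + v.offset_xy[1],
            v.z_frac * spec.spacing[2] * spec.grid_shape[2],
        ]
    )
    d = np.asarray(v.direction, dtype=float)
    return anchor, d / np.linalg.norm(d)


def _vessel_distance(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray | None:
    if spec.vessel is None:
        return None
    anchor, d = vessel_line(spec)
    rel = pts - anchor
    cross = np.cross(rel, d)
    return np.linalg.norm(cross, axis=-1)


def _elliptic_radius_sq(spec: PhantomSpec, pts: np.ndarray, t: float) -> np.ndarray:
    axes = spec.semi_axes_at(t)
    if (axes == 0).any():
        return np.full(pts.shape[:-1], np.inf)
    d = (pts - spec.center) / axes
    return np.einsum("...k,...k->...", d, d)


def temperature_at(spec: PhantomSpec, pts: np.ndarray, t: float) -> np.ndarray:
    """Noiseless temperature (°C) at world points ``pts`` (…, 3) at time t.

    Gaussian in the scaled elliptic radius ρ, normalized so T(ρ=1) equals
    the sector's coagulation threshold; inside the vessel cooling radius the
    field is clamped 1 °C below threshold so the heat sink carves an exact
    dent in the τ-level set.
    """
    pts = np.asarray(pts, dtype=float)
    rho2 = _elliptic_radius_sq(spec, pts, t)
    theta = np.degrees(
        np.arctan2(pts[..., 1] - spec.axis.y, pts[..., 0] - spec.axis.x)
    ) % 360.0
    tau = _sector_thresholds_at(spec, theta)
    base, peak = spec.baseline_temp_c, spec.peak_temp_c
    k = np.log((peak - base) / (tau - base))
    with np.errstate(over="ignore"):
        temp = base + (peak - base) * np.exp(-k * rho2)
    dv = _vessel_distance(spec, pts)
    if dv is not None:
        # cooling is strongest at the tube wall (flowing water near baseline)
        # and decays outward, reaching τ−1 °C at the cooling radius; the
        # τ-level set is therefore dented exactly at the cooling radius and
        # lower thresholds only thin the sheath, never dissolve it
        wall = spec.vessel.outer_radius_mm
        ramp = np.clip(
            (dv - wall) / max(spec.vessel.cooling_radius_mm - wall, 1e-9),
            0.0,
            1.0,
        )
        sheath = base + (tau - 1.0 - base) * ramp
        cooled = dv <= spec.vessel.cooling_radius_mm
        temp = np.where(cooled, np.minimum(temp, sheath), temp)
    return temp


def ground_truth_at(spec: PhantomSpec, pts: np.ndarray, t: float) -> np.ndarray:
    """Analytic necrosis indicator at world points: ellipsoid minus vessel sheath."""
    pts = np.asarray(pts, dtype=float)
    inside = _elliptic_radius_sq(spec, pts, t) <= 1.0
    dv = _vessel_distance(spec, pts)
    if dv is not None:
        inside &= dv > spec.vessel.cooling_radius_mm
    return inside


def _grid_points(grid: VoxelGrid) -> np.ndarray:
    xs, ys, zs = grid.axis_coords()
    return np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)


def generate_ground_truth(spec: PhantomSpec, t: float) -> VoxelGrid:
    """Binary ground-truth necrosis volume at time t (single connected blob)."""
    grid = spec.make_grid(dtype=np.uint8)
    mask = ground_truth_at(spec, _grid_points(grid), t)
    grid.values[:] = mask.astype(np.uint8)
    return grid


def simulate_temperature_field(spec: PhantomSpec, t: float) -> VoxelGrid:
    """3D temperature field (°C) at time t, with seeded additive noise.

    Noise: N(0, noise_sd) everywhere, plus N(0, background_noise_sd) outside
    the ROI cylinder (emulating air outside the phantom).  Bit-reproducible
    for a fixed spec seed and time.
    """
    grid = spec.make_grid()
    pts = _grid_points(grid)
    temp = temperature_at(spec, pts, t)
    rng = np.random.default_rng([int(spec.seed) % (2**31), 104729, int(round(t))])
    if spec.noise_sd > 0:
        temp = temp + rng.normal(0.0, spec.noise_sd, temp.shape)
    if spec.background_noise_sd > 0:
        r = np.hypot(pts[..., 0] - spec.axis.x, pts[..., 1] - spec.axis.y)
        bg = rng.normal(0.0, spec.background_noise_sd, temp.shape)
        temp = temp + np.where(r > spec.roi_size_mm / 2.0, bg, 0.0)
    grid.values[:] = temp
    return grid


def _slice_pixel_points(
    spec: PhantomSpec, angle_deg: float, nu: int, nv: int, u0: int
) -> np.ndarray:
    """World coordinates of every pixel of a rotated slice plane."""
    u = (np.arange(nu) - u0) * 1.0  # 1.0 mm in-plane spacing
    z = np.arange(nv) * spec.spacing[2]
    th = np.deg2rad(angle_deg)
    uu, zz = np.meshgrid(u, z, indexing="ij")
    return np.stack(
        [
            spec.axis.x + uu * np.cos(th),
            spec.axis.y + uu * np.sin(th),
            zz,
        ],
        axis=-1,
    )


def sample_slice_series(
    spec: PhantomSpec,
    timestamps: Sequence[float],
    n_orientations: int | None = None,
) -> OrientedSliceSeries:
    """Acquire the rotated temperature-slice time series.

    Each slice samples the analytic field on its plane at 1.0×1.0 mm
    in-plane spacing (u across the axis, z along it) and adds seeded noise.
    Slices listed in the spec's outlier schedule additionally receive
    half-normal low-SNR corruption noise (sd ``outlier_noise_sd``), which
    inflates their thresholded area by far more than 80%.
    """
    n = n_orientations or spec.n_orientations
    if n < 2:
        raise ValueError("need at least 2 orientations")
    angles = np.arange(n) * (180.0 / n)
    nu = spec.grid_shape[0]
    nv = spec.grid_shape[2]
    u0 = nu // 2
    slices = []
    for ti, t in enumerate(sorted(timestamps)):
        for oi, ang in enumerate(angles):
            pts = _slice_pixel_points(spec, float(ang), nu, nv, u0)
            temp = temperature_at(spec, pts, float(t))
            rng = np.random.default_rng(
                [int(spec.seed) % (2**31), 15485863, ti, oi]
            )
            if spec.noise_sd > 0:
                temp = temp + rng.normal(0.0, spec.noise_sd, temp.shape)
            if spec.background_noise_sd > 0:
                rmm = np.abs((np.arange(nu) - u0))[:, None] * np.ones((1, nv))
                bg = rng.normal(0.0, spec.background_noise_sd, temp.shape)
                temp = temp + np.where(rmm > spec.roi_size_mm / 2.0, bg, 0.0)
            if (float(ang), float(t)) in spec.outlier_schedule:
                temp = temp + np.abs(
                    rng.normal(0.0, spec.outlier_noise_sd, temp.shape)
                )
            slices.append(
                OrientedSlice(
                    angle_deg=float(ang),
                    pixels=temp,
                    in_plane_spacing=(1.0, spec.spacing[2]),
                    slice_thickness=5.0,
                    timestamp=float(t),
                    u0=u0,
                    z0=0.0,
                )
            )
    return OrientedSliceSeries(slices)


def reslice_ground_truth(
    gt: VoxelGrid,
    axis: ApplicatorAxis,
    n_orientations: int = 8,
    in_plane_spacing: tuple[float, float] | None = None,
) -> OrientedSliceSeries:
    """Extract rotated binary slices from a ground-truth volume.

    Nearest-neighbor sampling of ``gt`` on each rotated plane; this is the
    "perfect input" condition used to probe the reconstruction algorithms
    independently of thermometry errors.
    """
    if not gt.is_binary():
        raise ValueError("ground truth must be binary")
    du = in_plane_spacing[0] if in_plane_spacing else gt.spacing[0]
    dz = in_plane_spacing[1] if in_plane_spacing else gt.spacing[2]
    nu = gt.shape[0]
    nv = gt.shape[2]
    u0 = nu // 2
    angles = np.arange(n_orientations) * (180.0 / n_orientations)
    origin = np.asarray(gt.origin)
    spacing = np.asarray(gt.spacing)
    slices = []
    for ang in angles:
        th = np.deg2rad(ang)
        u = (np.arange(nu) - u0) * du
        z = gt.origin[2] + np.arange(nv) * dz
        uu, zz = np.meshgrid(u, z, indexing="ij")
        pts = np.stack(
            [axis.x + uu * np.cos(th), axis.y + uu * np.sin(th), zz], axis=-1
        )
        idx = np.round((pts - origin) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(gt.shape)), axis=-1)
        vals = np.zeros(uu.shape, dtype=np.uint8)
        sel = idx[ok]
        vals[ok] = gt.values[sel[:, 0], sel[:, 1], sel[:, 2]].astype(np.uint8)
        slices.append(
            OrientedSlice(
                angle_deg=float(ang),
                pixels=vals,
                in_plane_spacing=(du, dz),
                timestamp=0.0,
                u0=u0,
                z0=gt.origin[2],
            )
        )
    return OrientedSliceSeries(slices)


def analytic_ellipsoid_volume_mm3(semi_axes: Sequence[float]) -> float:
    a, b, c = semi_axes
    return 4.0 / 3.0 * np.pi * a * b * c
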