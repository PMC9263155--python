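"""End-to-end reconstruction: slices → masks → outlier filter → backend.

One call of :func:`reconstruct` covers the live-monitoring loop at a single
reconstruction time t:

1. resolve the threshold policy (searching per-orientation optimal
   thresholds against resliced ground truth where the policy needs them);
2. threshold every acquired temperature slice inside the region of
   interest and denoise it to its largest connected component;
3. reject outlier slices by the relative-area-growth rule (the shape
   backends only; the interpolation baseline historically ran unfiltered);
4. dispatch to the chosen backend and optionally subtract a known vessel
   mask from the result (a-priori knowledge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import outliers as _outliers
from .delaunay import delaunay_reconstruct
from .geometry import (
    ApplicatorAxis,
    OrientedSlice,
    OrientedSliceSeries,
    VoxelGrid,
    half_plane_angles,
    slice_to_world,
)
from .interpolation import UnsupportedPolicyError, interp_reconstruct
from .mvee import mvee_reconstruct
from .phantom import reslice_ground_truth
from .splines import spline_reconstruct
from .thermometry import (
    GROUND_TRUTH_SENTINEL,
    ThresholdPolicy,
    largest_connected_component,
    optimal_threshold_search,
    resolve_policy,
)

__all__ = [
    "METHODS",
    "ReconstructionResult",
    "necrosis_mask",
    "points_by_level",
    "per_orientation_optima",
    "reconstruct",
]

METHODS = ("interpolation", "delaunay", "mvee", "splines")

#: backends that run the outlier filter by default
FILTERED_METHODS = ("delaunay", "mvee", "splines")


@dataclass
class ReconstructionResult:
    """Output of one reconstruction: the mask plus its provenance."""

    mask: VoxelGrid
    method: str
    thresholds_c: list[float] | str
    outlier_log: list = field(default_factory=list)
    optima_c: list[float] | None = None


def _roi_window(n: int, center: int, size_px: int) -> tuple[int, int]:
    """Clamp a centered window of ``size_px`` into [0, n)."""
    half = size_px // 2
    lo = max(0, center - half)
    hi = min(n, lo + size_px)
    lo = max(0, hi - size_px)
    return lo, hi


def necrosis_mask(
    sl: OrientedSlice,
    tau_c: float,
    roi_size_mm: float = 60.0,
    z_center_px: int | None = None,
) -> np.ndarray:
    """Threshold one temperature slice inside the ROI window.

    Pixels outside the 60×60 mm window centered on the applicator column
    (and on ``z_center_px`` along the axis) are background and stay 0; the
    thresholded ROI is reduced to its largest 8-connected component.
    """
    nu, nz = sl.shape
    du, dz = sl.in_plane_spacing
    iu = _roi_window(nu, int(round(sl.u0)), int(round(roi_size_mm / du)))
    zc = nz // 2 if z_center_px is None else z_center_px
    iz = _roi_window(nz, zc, int(round(roi_size_mm / dz)))
    window = np.asarray(sl.pixels)[iu[0] : iu[1], iz[0] : iz[1]]
    sub = largest_connected_component(window >= tau_c)
    out = np.zeros((nu, nz), dtype=np.uint8)
    out[iu[0] : iu[1], iz[0] : iz[1]] = sub
    return out


def points_by_level(
    masks: list[OrientedSlice], grid: VoxelGrid, axis: ApplicatorAxis
) -> dict[int, np.ndarray]:
    """Gather in-plane world (x, y) of necrotic pixels per grid z-level."""
    levels: dict[int, list[np.ndarray]] = {}
    for sl in masks:
        idx = np.argwhere(np.asarray(sl.pixels) > 0)
        if len(idx) == 0:
            continue
        pts = slice_to_world(sl, idx, axis)
        zi = np.round((pts[:, 2] - grid.origin[2]) / grid.spacing[2]).astype(int)
        for z in np.unique(zi):
            levels.setdefault(int(z), []).append(pts[zi == z, :2])
    return {
        z: np.unique(np.round(np.vstack(chunks), 6), axis=0)
        for z, chunks in levels.items()
    }


def per_orientation_optima(
    series_t: OrientedSliceSeries,
    gt: VoxelGrid,
    axis: ApplicatorAxis,
    roi_size_mm: float = 60.0,
    step_c: float = 0.5,
) -> list[float]:
    """Optimal threshold per orientation: best Dice vs the resliced ground truth."""
    gt_slices = {
        s.angle_deg: s
        for s in reslice_ground_truth(gt, axis, series_t.n_orientations)
    }
    optima = []
    for ang in series_t.angles:
        sl = series_t.orientation(ang)[-1]
        gs = gt_slices[ang]
        nu, nz = sl.shape
        du, dz = sl.in_plane_spacing
        iu = _roi_window(nu, int(round(sl.u0)), int(round(roi_size_mm / du)))
        iz = _roi_window(nz, nz // 2, int(round(roi_size_mm / dz)))
        temp_roi = np.asarray(sl.pixels)[iu[0] : iu[1], iz[0] : iz[1]]
        gt_roi = np.asarray(gs.pixels)[iu[0] : iu[1], iz[0] : iz[1]]
        optima.append(optimal_threshold_search(temp_roi, gt_roi, step=step_c))
    return optima


def _masks_over_time(
    series: OrientedSliceSeries,
    taus_by_angle: dict[float, float],
    roi_size_mm: float,
) -> dict[float, list[tuple[float, OrientedSlice]]]:
    """Per-orientation time series of binary mask slices."""
    out: dict[float, list[tuple[float, OrientedSlice]]] = {}
    for ang in series.angles:
        frames = []
        for sl in series.orientation(ang):
            m = necrosis_mask(sl, taus_by_angle[ang], roi_size_mm)
            msl = OrientedSlice(
                angle_deg=sl.angle_deg,
                pixels=m,
                in_plane_spacing=sl.in_plane_spacing,
                slice_thickness=sl.slice_thickness,
                timestamp=sl.timestamp,
                u0=sl.u0,
                z0=sl.z0,
            )
            frames.append((sl.timestamp, msl))
        out[ang] = frames
    return out


def _filter_outliers(
    mask_frames: dict[float, list[tuple[float, OrientedSlice]]],
    pixel_area_mm2: float,
    threshold_pct: float,
):
    """Run the growth-rule filter on mask slices; returns accepted frames + log."""
    raw = {
        ang: [(t, np.asarray(m.pixels)) for t, m in frames]
        for ang, frames in mask_frames.items()
    }
    accepted, log = _outliers.filter_series(
        raw, pixel_area_mm2=pixel_area_mm2, threshold_pct=threshold_pct
    )
    kept: dict[float, list[tuple[float, OrientedSlice]]] = {}
    for ang, frames in mask_frames.items():
        ok_times = {t for t, _ in accepted[ang]}
        kept[ang] = [(t, m) for t, m in frames if t in ok_times]
    return kept, log


def _latest_accepted(
    frames: dict[float, list[tuple[float, OrientedSlice]]], t: float
) -> list[OrientedSlice]:
    """Most recent accepted mask per orientation at reconstruction time t."""
    out = []
    for ang, seq in frames.items():
        upto = [m for ts, m in seq if ts <= t + 1e-9]
        if upto:
            out.append(upto[-1])
    return out


def reconstruct(
    series: OrientedSliceSeries,
    method: str,
    policy: ThresholdPolicy,
    grid: VoxelGrid,
    axis: ApplicatorAxis,
    gt: VoxelGrid | None = None,
    t: float | None = None,
    roi_size_mm: float = 60.0,
    baseline_temp_c: float = 20.0,
    outlier_threshold_pct: float = _outliers.DEFAULT_GROWTH_THRESHOLD_PCT,
    outlier_filtering: bool | None = None,
    subtract_vessel: VoxelGrid | None = None,
    threshold_step_c: float = 0.5,
    seed: int = 0,
) -> ReconstructionResult:
    """Reconstruct the 3D necrosis mask at time t with one backend.

    ``series`` holds temperature slices (°C).  ``gt`` is required for the
    median/local/ground-truth policies (threshold optimization and perfect
    input, respectively).  ``outlier_filtering`` defaults to on for the
    shape backends and off for the interpolation baseline.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if t is None:
        t = series.timestamps[-1]
    if outlier_filtering is None:
        outlier_filtering = method in FILTERED_METHODS
    n_orient = series.n_orientations

    if method == "interpolation" and policy.mode == "local":
        raise UnsupportedPolicyError(
            "local thresholds cannot be applied to the interpolation method: "
            "its necrosis estimate comes from thresholding the fused volume"
        )

    optima = None
    if policy.mode in ("median", "local") and policy.per_orientation_values is None:
        if gt is None:
            raise ValueError(f"{policy.mode} policy needs a ground truth")
        optima = per_orientation_optima(
            series.at_time(t), gt, axis, roi_size_mm, threshold_step_c
        )
    taus = resolve_policy(policy, optima, n_orient)

    log: list = []
    if taus == GROUND_TRUTH_SENTINEL:
        if gt is None:
            raise ValueError("ground-truth policy needs a ground truth volume")
        masks = list(reslice_ground_truth(gt, axis, n_orient))
        masks = [
            OrientedSlice(
                angle_deg=m.angle_deg,
                pixels=largest_connected_component(
                    np.asarray(m.pixels) > 0
                ).astype(np.uint8),
                in_plane_spacing=m.in_plane_spacing,
                slice_thickness=m.slice_thickness,
                timestamp=m.timestamp,
                u0=m.u0,
                z0=m.z0,
            )
            for m in masks
        ]
    else:
        taus_by_angle = dict(zip(series.angles, taus))
        frames = _masks_over_time(series, taus_by_angle, roi_size_mm)
        if outlier_filtering:
            px_area = (
                series.slices[0].in_plane_spacing[0]
                * series.slices[0].in_plane_spacing[1]
            )
            frames, log = _filter_outliers(frames, px_area, outlier_threshold_pct)
        masks = _latest_accepted(frames, t)

    if method == "interpolation":
        if taus == GROUND_TRUTH_SENTINEL:
            raise UnsupportedPolicyError(
                "the interpolation method reconstructs a heat map; resliced "
                "ground-truth masks carry no temperatures"
            )
        slices_t = list(series.at_time(t))
        mask = interp_reconstruct(
            slices_t,
            taus[0],
            grid,
            axis,
            roi_radius_mm=roi_size_mm / 2.0,
            baseline_temp_c=baseline_temp_c,
        )
    elif method == "delaunay":
        mask = delaunay_reconstruct(masks, grid, axis, seed=seed)
    else:
        pbl = points_by_level(masks, grid, axis)
        if method == "mvee":
            mask = mvee_reconstruct(pbl, grid)
        else:
            step = 180.0 / n_orient
            mask = spline_reconstruct(pbl, grid, axis, step)

    if subtract_vessel is not None:
        if not mask.same_geometry(subtract_vessel):
            raise ValueError("vessel mask geometry does not match the grid")
        mask = VoxelGrid(
            (mask.values.astype(bool) & ~subtract_vessel.values.astype(bool)).astype(
                np.uint8
            ),
            mask.spacing,
            mask.origin,
        )

    return ReconstructionResult(
        mask=mask,
        method=method,
        thresholds_c=taus if isinstance(taus, str) else [float(v) for v in taus],
        outlier_log=log,
        optima_c=None if optima is None else [float(v) for v in optima],
    )
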