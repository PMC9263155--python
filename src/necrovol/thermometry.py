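"""Phase-to-temperature mapping and necrosis thresholding.

Temperature maps come from the proton resonance frequency shift (PRFS): the
water proton resonance frequency decreases linearly with temperature, so the
phase difference between a gradient-echo image and a pre-heating reference
encodes the temperature change,

    ΔT = Δφ / (2π · γ · α · B0 · TE),

with γ the gyromagnetic ratio, α the PRF change coefficient (≈ −0.01 ppm/°C),
B0 the field strength and TE the echo time.  Necrosis is then declared by the
critical-temperature model: a pixel is coagulated once its temperature reaches
a phantom-specific threshold (50–60 °C), with no cumulative-dose accounting.

Threshold policies
------------------
``global``        one fixed threshold for every orientation.
``median``        median of the eight per-orientation optimal thresholds.
``local``         each orientation keeps its own optimum.
``ground_truth``  bypass thresholding; masks come from resliced ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "PrfsConstants",
    "ThresholdPolicy",
    "GROUND_TRUTH_SENTINEL",
    "prfs_temperature",
    "phase_from_temperature",
    "crop_roi",
    "largest_connected_component",
    "threshold_slice",
    "optimal_threshold_search",
    "resolve_policy",
]

#: sentinel returned by resolve_policy in ground-truth mode
GROUND_TRUTH_SENTINEL = "ground_truth"


@dataclass(frozen=True)
class PrfsConstants:
    """PRFS thermometry constants (1.5 T GRE defaults, TE = 3.69 ms)."""

    alpha_ppm_per_c: float = -0.01
    gamma_mhz_per_t: float = 42.58
    b0_t: float = 1.5
    te_s: float = 3.69e-3
    baseline_temp_c: float = 20.0

    def __post_init__(self) -> None:
        if self.te_s <= 0 or self.b0_t <= 0:
            raise ValueError("TE and B0 must be positive")

    @property
    def rad_per_degc(self) -> float:
        """Phase change (radians) per °C of heating."""
        return (
            2.0
            * np.pi
            * self.gamma_mhz_per_t
            * 1e6
            * self.alpha_ppm_per_c
            * 1e-6
            * self.b0_t
            * self.te_s
        )


@dataclass
class ThresholdPolicy:
    """How per-orientation coagulation thresholds are chosen."""

    mode: Literal["global", "median", "local", "ground_truth"] = "median"
    global_value: float | None = None
    per_orientation_values: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.mode == "global" and self.global_value is None:
            raise ValueError("global policy requires global_value")


def _wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences to (−π, π]."""
    return np.pi - np.mod(np.pi - dphi, 2.0 * np.pi)


def prfs_temperature(
    phase_t: np.ndarray, phase_ref: np.ndarray, k: PrfsConstants = PrfsConstants()
) -> np.ndarray:
    """Temperature map (°C) from a phase image and its reference.

    The phase difference is wrapped to (−π, π] before scaling, so the map is
    unambiguous as long as the true heating stays within the ±π phase window.
    """
    phase_t = np.asarray(phase_t, dtype=float)
    phase_ref = np.asarray(phase_ref, dtype=float)
    if phase_t.shape != phase_ref.shape:
        raise ValueError("phase images must have the same shape")
    dphi = _wrap_phase(phase_t - phase_ref)
    return k.baseline_temp_c + dphi / k.rad_per_degc


def phase_from_temperature(
    temp: np.ndarray, phase_ref: np.ndarray, k: PrfsConstants = PrfsConstants()
) -> np.ndarray:
    """Synthesize the heated phase image that would produce ``temp``.

    Inverse of :func:`prfs_temperature` (up to 2π wraps); used for round-trip
    simulation of phase-based input.
    """
    temp = np.asarray(temp, dtype=float)
    dphi = (temp - k.baseline_temp_c) * k.rad_per_degc
    return _wrap_phase(np.asarray(phase_ref, dtype=float) + dphi)


def crop_roi(
    image: np.ndarray,
    center_px: tuple[int, int],
    size_mm: float = 60.0,
    spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Crop the square region of interest centered on the applicator.

    The default 60×60 mm window suppresses background (air) outside the
    phantom.  Raises if the window does not fit inside the image.
    """
    image = np.asarray(image)
    n0 = int(round(size_mm / spacing_mm[0]))
    n1 = int(round(size_mm / spacing_mm[1]))
    i0 = int(center_px[0]) - n0 // 2
    j0 = int(center_px[1]) - n1 // 2
    if i0 < 0 or j0 < 0 or i0 + n0 > image.shape[0] or j0 + n1 > image.shape[1]:
        raise ValueError("ROI exceeds image bounds")
    return image[i0 : i0 + n0, j0 : j0 + n1]


def largest_connected_component(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Keep only the largest foreground component (8-connected in 2D).

    Ties are broken toward the component whose lexicographically smallest
    pixel index is smallest, making the result deterministic.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    labels = measure.label(mask, connectivity=connectivity)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        # tie-break: component containing the smallest (row, col) pixel
        order = np.argwhere(labels > 0)
        order = order[np.lexsort(order.T[::-1])]
        for px in order:
            if labels[tuple(px)] in best:
                winner = labels[tuple(px)]
                break
    else:
        winner = best[0]
    return labels == winner


def threshold_slice(
    temp: np.ndarray, tau: float, connectivity: int = 2
) -> np.ndarray:
    """Binary necrosis mask {T ≥ τ}, denoised to its largest component."""
    return largest_connected_component(np.asarray(temp) >= tau, connectivity)


def optimal_threshold_search(
    temp: np.ndarray,
    gt_slice: np.ndarray,
    lo: float = 0.0,
    hi: float = 100.0,
    step: float = 0.5,
) -> float:
    """Threshold in [lo, hi] maximizing the Dice overlap with a ground-truth slice.

    Scans the range at ``step`` resolution; ties resolve toward the larger
    threshold.  An empty ground-truth slice returns ``hi`` with a warning.
    """
    temp = np.asarray(temp, dtype=float)
    gt = np.asarray(gt_slice).astype(bool)
    if temp.shape != gt.shape:
        raise ValueError("temperature and ground-truth slices must match")
    if not gt.any():
        warnings.warn("empty ground-truth slice; returning upper bound")
        return float(hi)
    taus = np.arange(lo, hi + step / 2, step)
    best_tau, best_dsc = float(hi), -1.0
    n_gt = gt.sum()
    for tau in taus:
        m = threshold_slice(temp, tau)
        inter = np.logical_and(m, gt).sum()
        denom = m.sum() + n_gt
        d = 2.0 * inter / denom if denom else 1.0
        if d >= best_dsc:  # >= : ties go to the larger tau
            best_dsc, best_tau = d, float(tau)
    return best_tau


def resolve_policy(
    policy: ThresholdPolicy,
    per_orientation_optima: Sequence[float] | None = None,
    n_orientations: int = 8,
):
    """Expand a threshold policy into one threshold per orientation.

    Returns a list of n_orientations thresholds, or the
    :data:`GROUND_TRUTH_SENTINEL` string for the ground-truth policy (masks
    then come from reslicing the ground truth, bypassing thresholds).
    """
    if policy.mode == "ground_truth":
        return GROUND_TRUTH_SENTINEL
    if policy.mode == "global":
        return [float(policy.global_value)] * n_orientations
    optima = (
        per_orientation_optima
        if per_orientation_optima is not None
        else policy.per_orientation_values
    )
    if optima is None:
        raise ValueError(f"{policy.mode} policy requires per-orientation optima")
    optima = [float(v) for v in optima]
    if len(optima) != n_orientations:
        raise ValueError(
            f"{policy.mode} policy needs {n_orientations} optima, got {len(optima)}"
        )
    if policy.mode == "median":
        return [float(np.median(optima))] * n_orientations
    if policy.mode == "local":
        return list(optima)
    raise ValueError(f"unknown policy mode {policy.mode!r}")
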