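"""Rejection of corrupted slices from the live stream.

A microwave-ablation necrosis zone only ever grows, so a sudden jump in the
thresholded necrosis area of one orientation betrays a low-SNR artifact
rather than real coagulation.  For each orientation the area of the current
(component-denoised) mask is compared with the most recent *accepted* mask of
the same orientation; a relative change

    ΔA = |A_t − A_prev| · 100 / A_prev   [%]

strictly above the threshold (80% by default, chosen empirically in the
source study) flags the slice, which is excluded from the current
reconstruction but kept in the log.  Comparing against the last accepted
mask — not the raw previous frame — keeps a single corrupted frame from
flagging the healthy frame that follows it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthRecord",
    "relative_growth",
    "is_outlier",
    "filter_series",
    "growth_log_frame",
]

DEFAULT_GROWTH_THRESHOLD_PCT = 80.0


@dataclass(frozen=True)
class GrowthRecord:
    """One orientation/timestep growth measurement."""

    angle_deg: float
    t_prev: float
    t_curr: float
    area_prev_mm2: float
    area_curr_mm2: float
    delta_pct: float
    outlier: bool


def relative_growth(area_curr: float, area_prev: float) -> float:
    """Relative area change in percent; +inf when growing from zero area."""
    if area_curr < 0 or area_prev < 0:
        raise ValueError("areas must be non-negative")
    if area_prev == 0:
        return 0.0 if area_curr == 0 else math.inf
    return abs(area_curr - area_prev) * 100.0 / area_prev


def is_outlier(
    delta_pct: float, threshold_pct: float = DEFAULT_GROWTH_THRESHOLD_PCT
) -> bool:
    """True iff the relative change *strictly* exceeds the threshold."""
    return delta_pct > threshold_pct


def filter_series(
    mask_series: dict[float, list[tuple[float, np.ndarray]]],
    pixel_area_mm2: float = 1.0,
    threshold_pct: float = DEFAULT_GROWTH_THRESHOLD_PCT,
) -> tuple[dict[float, list[tuple[float, np.ndarray]]], list[GrowthRecord]]:
    """Flag outlier masks per orientation and drop them from the series.

    Parameters
    ----------
    mask_series : dict
        ``{angle_deg: [(timestamp, binary mask), ...]}`` — masks already
        denoised by connected-component analysis, time-ordered per angle.
    pixel_area_mm2 : float
        Area of one mask pixel, to report areas in mm².

    Returns
    -------
    accepted : dict
        Same structure with flagged entries removed.
    log : list of GrowthRecord
        One record per comparison (the first frame of each orientation has
        no predecessor and is never flagged, hence never logged).
    """
    accepted: dict[float, list[tuple[float, np.ndarray]]] = {}
    log: list[GrowthRecord] = []
    for angle, frames in mask_series.items():
        frames = sorted(frames, key=lambda f: f[0])
        kept: list[tuple[float, np.ndarray]] = []
        ref_t: float | None = None
        ref_area: float | None = None
        for t, mask in frames:
            area = float(np.count_nonzero(mask)) * pixel_area_mm2
            if ref_area is None:
                kept.append((t, mask))
                ref_t, ref_area = t, area
                continue
            delta = relative_growth(area, ref_area)
            flagged = is_outlier(delta, threshold_pct)
            log.append(
                GrowthRecord(angle, ref_t, t, ref_area, area, delta, flagged)
            )
            if not flagged:
                kept.append((t, mask))
                ref_t, ref_area = t, area
        accepted[angle] = kept
    return accepted, log


def growth_log_frame(log: list[GrowthRecord]) -> pd.DataFrame:
    """Growth log as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "orientation_deg": r.angle_deg,
                "t_prev_s": r.t_prev,
                "t_curr_s": r.t_curr,
                "area_prev_mm2": r.area_prev_mm2,
                "area_curr_mm2": r.area_curr_mm2,
                "delta_pct": r.delta_pct,
                "outlier": r.outlier,
            }
            for r in log
        ],
        columns=[
            "orientation_deg",
            "t_prev_s",
            "t_curr_s",
            "area_prev_mm2",
            "area_curr_mm2",
            "delta_pct",
            "outlier",
        ],
    )
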