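"""NIfTI and sidecar I/O.

Volumes travel as NIfTI (.nii/.nii.gz) with spacing and origin taken from
the header affine, never from configuration.  A slice series is a directory
of 2D NIfTI files plus one ``series.yaml`` sidecar listing, per file, the
rotation angle, timestamp, in-plane spacing, slice thickness and the axis
pixel — everything the geometry module needs to place the plane in space.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .geometry import OrientedSlice, OrientedSliceSeries, VoxelGrid

__all__ = [
    "save_grid",
    "load_grid",
    "save_slice_series",
    "load_slice_series",
]

SIDECAR_NAME = "series.yaml"


def save_grid(grid: VoxelGrid, path: str | Path) -> None:
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_grid(path: str | Path) -> VoxelGrid:
    img = nib.load(str(path))
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
    spacing = tuple(float(abs(affine[k, k])) for k in range(3))
    origin = tuple(float(affine[k, 3]) for k in range(3))
    return VoxelGrid(np.asarray(img.dataobj, dtype=float), spacing, origin)


def save_slice_series(series: OrientedSliceSeries, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, sl in enumerate(series):
        fname = f"slice_{k:04d}.nii.gz"
        img = nib.Nifti1Image(
            np.asarray(sl.pixels, dtype=np.float32), np.eye(4)
        )
        nib.save(img, str(directory / fname))
        entries.append(
            {
                "file": fname,
                "angle_deg": float(sl.angle_deg),
                "timestamp_s": float(sl.timestamp),
                "in_plane_spacing_mm": [float(s) for s in sl.in_plane_spacing],
                "slice_thickness_mm": float(sl.slice_thickness),
                "u0_px": float(sl.u0),
                "z0_mm": float(sl.z0),
            }
        )
    sidecar = {"kind": "temperature", "slices": entries}
    with open(directory / SIDECAR_NAME, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def load_slice_series(directory: str | Path) -> OrientedSliceSeries:
    directory = Path(directory)
    with open(directory / SIDECAR_NAME) as fh:
        sidecar = yaml.safe_load(fh)
    slices = []
    for entry in sidecar["slices"]:
        img = nib.load(str(directory / entry["file"]))
        slices.append(
            OrientedSlice(
                angle_deg=float(entry["angle_deg"]),
                pixels=np.asarray(img.dataobj, dtype=float),
                in_plane_spacing=tuple(entry["in_plane_spacing_mm"]),
                slice_thickness=float(entry.get("slice_thickness_mm", 5.0)),
                timestamp=float(entry["timestamp_s"]),
                u0=float(entry["u0_px"]),
                z0=float(entry.get("z0_mm", 0.0)),
            )
        )
    return OrientedSliceSeries(slices)
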