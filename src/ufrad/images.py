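"""In-memory containers and NIfTI I/O for dynamic series and masks.

Volumes are indexed ``(slice, row, col)`` = (z, y, x); dynamic series add a
leading time axis, ``data[t, z, y, x]``.  On disk a series is stored as a
4D NIfTI with the time axis last (x, y, z, t), the conventional layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from ufrad.schedules import AcquisitionSchedule


@dataclass
class DceSeries:
    """One lesion's dynamic contrast-enhanced series.

    Attributes
    ----------
    data : ndarray, shape (T, nz, ny, nx)
    spacing_mm : (sz, sy, sx) voxel spacing
    schedule : AcquisitionSchedule
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    schedule: AcquisitionSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("series data must be 4D (t, z, y, x)")
        if self.data.shape[0] != self.schedule.n_frames:
            raise ValueError("time axis does not match schedule")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three positive values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def modality(self) -> str:
        return self.schedule.modality


def _affine(spacing_mm) -> np.ndarray:
    sz, sy, sx = spacing_mm
    return np.diag([sx, sy, sz, 1.0])


def save_series(series: DceSeries, path: str | Path) -> None:
    # (t,z,y,x) -> (x,y,z,t)
    arr = np.transpose(series.data, (3, 2, 1, 0)).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, _affine(series.spacing_mm)), str(path))


def load_series(path: str | Path, schedule: AcquisitionSchedule) -> DceSeries:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return DceSeries(np.transpose(arr, (3, 2, 1, 0)), spacing, schedule)


def save_mask(mask: np.ndarray, spacing_mm, path: str | Path) -> None:
    arr = np.transpose(np.asarray(mask, dtype=np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(arr, _affine(spacing_mm)), str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.transpose(arr, (2, 1, 0)).astype(bool), spacing
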