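"""Image normalization, isotropic resampling and gray-level discretization."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def normalize_image(vol: np.ndarray) -> np.ndarray:
    """Whole-volume z-score: (x - mean) / SD.  Errors on a constant image."""
    vol = np.asarray(vol, dtype=float)
    sd = vol.std()
    if sd == 0:
        raise ValueError("constant image cannot be normalized")
    return (vol - vol.mean()) / sd


def resample_isotropic(
    vol: np.ndarray,
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    target_mm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Resample image (linear) and mask (nearest) to isotropic spacing."""
    spacing = np.asarray(spacing_mm, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    if np.allclose(spacing, target_mm):
        return np.asarray(vol, dtype=float), np.asarray(mask, dtype=bool), (
            target_mm,
        ) * 3
    zoom = spacing / target_mm
    out_vol = ndimage.zoom(np.asarray(vol, dtype=float), zoom, order=1)
    out_mask = ndimage.zoom(
        np.asarray(mask, dtype=np.uint8), zoom, order=0, grid_mode=False
    ).astype(bool)
    if not out_mask.any():
        raise ValueError("mask is empty after resampling")
    return out_vol, out_mask, (target_mm,) * 3


def discretize(vol: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Fixed-bin-count discretization over the in-mask intensity range.

    Returns integer gray levels 1..n_bins inside the mask (0 outside).  A
    constant region maps to a single level.
    """
    vol = np.asarray(vol, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = vol[mask]
    lo, hi = vals.min(), vals.max()
    out = np.zeros(vol.shape, dtype=np.int32)
    if hi == lo:
        out[mask] = 1
        return out
    levels = np.floor((vol - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    out[mask] = np.clip(levels[mask], 1, n_bins)
    return out
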