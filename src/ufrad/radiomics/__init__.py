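"""Radiomic feature extraction with a fixed 1618-feature manifest.

Groups and counts: 17 first-order statistics, 7 shape descriptors, 162
texture features (GLCM per in-plane offset plus direction-averaged, GLRLM
per offset) and 1432 wavelet features (8 stationary-transform sub-bands x
(17 first-order + 162 texture)).  The manifest is generated by
:func:`build_manifest` and versioned via :data:`MANIFEST_VERSION`; the
counts per group, not the particular descriptor composition, are the
stable contract.

The extraction pipeline is: whole-volume z-score normalization ->
isotropic resampling (linear image / nearest-neighbor mask) -> bounding
box crop -> feature groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ufrad.radiomics.preprocess import normalize_image, resample_isotropic, discretize
from ufrad.radiomics.firstorder import FIRST_ORDER_NAMES, extract_first_order
from ufrad.radiomics.shape import SHAPE_NAMES, extract_shape
from ufrad.radiomics.texture import (
    GLCM_NAMES,
    GLRLM_NAMES,
    OFFSETS,
    extract_texture,
)
from ufrad.radiomics.wavelet import SUBBAND_ORDER, wavelet_features

MANIFEST_VERSION = "1.0"

GROUP_COUNTS = {"first_order": 17, "shape": 7, "texture": 162, "wavelet": 1432}
TOTAL_FEATURES = 1618


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered (group, name) pairs defining the feature vector layout."""

    entries: tuple[tuple[str, str], ...]
    version: str = MANIFEST_VERSION

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        names = set()
        for group, name in self.entries:
            counts[group] = counts.get(group, 0) + 1
            if name in names:
                raise ValueError(f"duplicate feature name {name!r}")
            names.add(name)
        if counts != GROUP_COUNTS:
            raise ValueError(f"group counts {counts} != required {GROUP_COUNTS}")

    @property
    def names(self) -> list[str]:
        return [name for _, name in self.entries]

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for group, _ in self.entries:
            counts[group] = counts.get(group, 0) + 1
        return counts


def _texture_names() -> list[str]:
    names = []
    for key in OFFSETS:
        names += [f"glcm_{n}_{key}" for n in GLCM_NAMES]
    names += [f"glcm_{n}_avg" for n in GLCM_NAMES]
    for key in OFFSETS:
        names += [f"glrlm_{n}_{key}" for n in GLRLM_NAMES]
    return names


def build_manifest() -> FeatureManifest:
    """The fixed 17 / 7 / 162 / 1432 feature manifest."""
    entries: list[tuple[str, str]] = []
    entries += [("first_order", f"fo_{n}") for n in FIRST_ORDER_NAMES]
    entries += [("shape", f"shape_{n}") for n in SHAPE_NAMES]
    entries += [("texture", n) for n in _texture_names()]
    for band in SUBBAND_ORDER:
        entries += [("wavelet", f"wav_{band}_fo_{n}") for n in FIRST_ORDER_NAMES]
        entries += [("wavelet", f"wav_{band}_{n}") for n in _texture_names()]
    return FeatureManifest(tuple(entries))


def _crop_bbox(vol: np.ndarray, mask: np.ndarray, pad: int = 8):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return vol[sl], mask[sl]


def extract_all(
    vol: np.ndarray,
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_bins: int = 32,
    wavelet: str = "coif1",
    resample: bool = True,
) -> pd.Series:
    """Full 1618-feature vector of one lesion volume.

    Returns a Series aligned to :func:`build_manifest` order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vol = normalize_image(vol)
    if resample:
        vol, mask, spacing_mm = resample_isotropic(vol, mask, spacing_mm)
    vol, mask = _crop_bbox(vol, mask)

    values: dict[str, float] = {}
    for name, v in extract_first_order(vol, mask, spacing_mm, n_bins).items():
        values[f"fo_{name}"] = v
    for name, v in extract_shape(mask, spacing_mm).items():
        values[f"shape_{name}"] = v
    values.update(extract_texture(vol, mask, n_bins))
    values.update(wavelet_features(vol, mask, spacing_mm, n_bins, wavelet))

    manifest = build_manifest()
    return pd.Series([values[n] for n in manifest.names], index=manifest.names)


__all__ = [
    "FeatureManifest",
    "MANIFEST_VERSION",
    "GROUP_COUNTS",
    "TOTAL_FEATURES",
    "build_manifest",
    "extract_all",
    "normalize_image",
    "resample_isotropic",
    "discretize",
    "extract_first_order",
    "extract_shape",
    "extract_texture",
    "wavelet_features",
]
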