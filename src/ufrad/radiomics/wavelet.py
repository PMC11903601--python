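"""Single-level 3D stationary wavelet decomposition features (1432 values).

The volume is decomposed once with an undecimated (stationary) transform
into the 8 low/high-pass sub-band combinations LLL..HHH (one letter per
axis, L = approximation, H = detail); being undecimated, each sub-band
keeps the original grid so the tumor mask applies directly.  On every
sub-band the 17 first-order and 162 texture features are recomputed:
8 x (17 + 162) = 1432.  Default wavelet: coif1 (compactly supported,
orthogonal).  Odd axes are edge-padded to even length and cropped back.
"""

from __future__ import annotations

import numpy as np
import pywt

from ufrad.radiomics.firstorder import extract_first_order
from ufrad.radiomics.texture import extract_texture

#: fixed sub-band order; pywt key letters a/d map to L/H per axis (z, y, x)
SUBBAND_ORDER = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def decompose(vol: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """8 same-shape sub-band images of a single-level stationary transform."""
    vol = np.asarray(vol, dtype=float)
    pads = [(0, s % 2) for s in vol.shape]
    padded = np.pad(vol, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    for key, band in coeffs.items():
        name = key.upper().replace("A", "L").replace("D", "H")
        out[name] = band[: vol.shape[0], : vol.shape[1], : vol.shape[2]]
    return {name: out[name] for name in SUBBAND_ORDER}


def wavelet_features(
    vol: np.ndarray,
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_bins: int = 32,
    wavelet: str = "coif1",
) -> dict[str, float]:
    """First-order + texture features on each of the 8 sub-bands."""
    out: dict[str, float] = {}
    for band_name, band in decompose(vol, wavelet).items():
        fo = extract_first_order(band, mask, spacing_mm, n_bins)
        for name, value in fo.items():
            out[f"wav_{band_name}_fo_{name}"] = value
        tx = extract_texture(band, mask, n_bins)
        for name, value in tx.items():
            out[f"wav_{band_name}_{name}"] = value
    return out
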