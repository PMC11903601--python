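"""Kinetic curve descriptors from dynamic series.

Ultrafast descriptors are measured on the time-signal curve of a 3 mm
hotspot ROI: U1 is the first post-contrast frame whose signal exceeds the
precontrast mean by 10%, U2 the next frame; time to enhancement (TTE) is
the tumor-minus-aorta onset difference in frames times the frame interval;
maximum slope is the steepest consecutive-frame segment of the relative
enhancement curve in %/s; the initial enhancement rate (IER) is the
precontrast-to-early signal ratio.

Standard-series CAD kinetics classify tumor voxels that enhance more than
50% at the initial post-contrast phase into washout (> 10% decline by the
delayed phase), persistent (> 10% rise) or plateau (within +-10%), and
report peak enhancement as the largest initial voxel enhancement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ufrad.images import DceSeries
from ufrad.schedules import AcquisitionSchedule, ULTRAFAST_INTERVAL_S

logger = logging.getLogger(__name__)

#: sentinel frame index for "onset never reached"
NO_ONSET: None = None


@dataclass
class TimeSignalCurve:
    """Mean ROI signal intensity as a function of acquisition time."""

    times: np.ndarray
    signal: np.ndarray
    n_precontrast: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError("times and signal must be matching 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 1 <= self.n_precontrast < self.times.size:
            raise ValueError("need >=1 precontrast and >=1 post-contrast frame")

    @property
    def baseline(self) -> float:
        return float(np.mean(self.signal[: self.n_precontrast]))


@dataclass
class HotspotRoi:
    """In-plane disc ROI; ``voxels`` lists the member (z, y, x) indices."""

    slice_index: int
    center: tuple[int, int]  # (row, col)
    diameter_mm: float
    voxels: np.ndarray  # (n, 3) int indices


@dataclass
class UltrafastKinetics:
    tte_s: float
    max_slope_pct_per_s: float
    initial_enhancement_rate: float
    u1_phase: int | None
    u2_phase: int | None
    u2_time_s: float

    def as_dict(self) -> dict[str, float]:
        return {
            "uf_kin_tte_s": self.tte_s,
            "uf_kin_max_slope_pct_per_s": self.max_slope_pct_per_s,
            "uf_kin_initial_enhancement_rate": self.initial_enhancement_rate,
            "uf_kin_u2_time_s": self.u2_time_s,
        }


@dataclass
class StandardKinetics:
    peak_enhancement_pct: float
    washout_pct: float
    plateau_pct: float
    persistent_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "std_kin_peak_enhancement_pct": self.peak_enhancement_pct,
            "std_kin_washout_pct": self.washout_pct,
            "std_kin_plateau_pct": self.plateau_pct,
            "std_kin_persistent_pct": self.persistent_pct,
        }


@dataclass
class KineticsConfig:
    """Tunable thresholds of the kinetic extraction.

    frame_interval_s : ultrafast frame spacing used in the TTE formula.
    onset_threshold : fractional rise over the precontrast mean defining
        enhancement onset (U1 rule), default 0.10.
    ier_convention : "as_printed" (precontrast / early signal) or
        "relative_change" ((early - precontrast) / precontrast).
    enh_threshold : initial enhancement fraction a voxel must exceed to be
        evaluated by the CAD rule, default 0.50.
    delta : washout/persistent classification boundary, default 0.10.
    """

    frame_interval_s: float = ULTRAFAST_INTERVAL_S
    onset_threshold: float = 0.10
    ier_convention: str = "as_printed"
    enh_threshold: float = 0.50
    delta: float = 0.10
    hotspot_diameter_mm: float = 3.0


def _disc_offsets(diameter_mm: float, spacing_yx: tuple[float, float]) -> np.ndarray:
    """In-plane (dy, dx) offsets whose voxel centers lie within the disc."""
    r = diameter_mm / 2.0
    sy, sx = spacing_yx
    ny = int(np.floor(r / sy))
    nx = int(np.floor(r / sx))
    offs = [
        (dy, dx)
        for dy in range(-ny, ny + 1)
        for dx in range(-nx, nx + 1)
        if (dy * sy) ** 2 + (dx * sx) ** 2 <= r**2 + 1e-9
    ]
    return np.asarray(offs, dtype=int)


def find_hotspot(
    series: DceSeries, mask: np.ndarray, diameter_mm: float = 3.0
) -> HotspotRoi:
    """Place the disc ROI maximizing mean relative enhancement on the last frame.

    The heat map is the relative enhancement of the last frame over the
    precontrast frame(s); candidate disc centers are the mask voxels and
    ties are broken toward the lowest (slice, row, col) index.  If the mask
    holds fewer voxels than the disc, the disc is intersected with the mask
    (with a warning).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    n_pre = series.schedule.n_precontrast
    pre = series.data[:n_pre].mean(axis=0)
    last = series.data[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        relmap = np.where(pre > 0, (last - pre) / pre, -np.inf)

    offsets = _disc_offsets(diameter_mm, (series.spacing_mm[1], series.spacing_mm[2]))
    _, ny, nx = series.grid_shape
    shrink = mask.sum() < len(offsets)
    if shrink:
        warnings.warn("mask smaller than hotspot disc; shrinking ROI to mask voxels")

    # score every mask voxel as a candidate center, vectorized over offsets
    score_sum = np.zeros_like(relmap)
    score_cnt = np.zeros_like(relmap)
    for dy, dx in offsets:
        ys = slice(max(0, dy), ny + min(0, dy))
        xs = slice(max(0, dx), nx + min(0, dx))
        yt = slice(max(0, -dy), ny + min(0, -dy))
        xt = slice(max(0, -dx), nx + min(0, -dx))
        score_sum[:, yt, xt] += relmap[:, ys, xs]
        score_cnt[:, yt, xt] += 1.0
    score = np.where(mask, score_sum / score_cnt, -np.inf)
    flat = int(np.argmax(score))  # first occurrence = lowest (z, y, x)
    z, y, x = np.unravel_index(flat, score.shape)

    vox = []
    for dy, dx in offsets:
        yy, xx = y + dy, x + dx
        if 0 <= yy < ny and 0 <= xx < nx and not (shrink and not mask[z, yy, xx]):
            vox.append((z, yy, xx))
    return HotspotRoi(int(z), (int(y), int(x)), diameter_mm, np.asarray(vox))


def extract_curve(series: DceSeries, roi: HotspotRoi) -> TimeSignalCurve:
    """Per-frame mean signal over the ROI voxels."""
    z, y, x = roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]
    sig = series.data[:, z, y, x].mean(axis=1)
    return TimeSignalCurve(series.schedule.times, sig, series.schedule.n_precontrast)


def onset_phase(curve: TimeSignalCurve, threshold_frac: float = 0.10) -> int | None:
    """First post-contrast frame exceeding baseline by ``threshold_frac``.

    Returns ``None`` if the curve never enhances past the threshold.
    """
    base = curve.baseline
    if base <= 0:
        raise ValueError("non-positive baseline; onset threshold undefined")
    thr = (1.0 + threshold_frac) * base
    post = np.nonzero(curve.signal[curve.n_precontrast :] > thr)[0]
    if post.size == 0:
        return NO_ONSET
    return int(post[0]) + curve.n_precontrast


def compute_tte(
    tumor_curve: TimeSignalCurve,
    aorta_curve: TimeSignalCurve,
    frame_interval_s: float = ULTRAFAST_INTERVAL_S,
    threshold_frac: float = 0.10,
) -> float:
    """(tumor onset phase - aorta onset phase) x frame interval, in seconds.

    NaN if either onset is never reached.
    """
    t_on = onset_phase(tumor_curve, threshold_frac)
    a_on = onset_phase(aorta_curve, threshold_frac)
    if t_on is None or a_on is None:
        logger.warning("TTE undefined: tumor onset %s, aorta onset %s", t_on, a_on)
        return float("nan")
    return (t_on - a_on) * frame_interval_s


def compute_max_slope(curve: TimeSignalCurve) -> float:
    """Steepest consecutive-frame slope of relative enhancement, in %/s."""
    base = curve.baseline
    if base <= 0:
        raise ValueError("non-positive baseline; relative enhancement undefined")
    rel = 100.0 * (curve.signal - base) / base
    slopes = np.diff(rel) / np.diff(curve.times)
    return float(np.max(slopes))


def compute_ier(
    curve: TimeSignalCurve, early_phase: int, convention: str = "as_printed"
) -> float:
    """Initial enhancement rate at the given early phase.

    ``as_printed`` is the precontrast-mean / early-signal ratio; the
    ``relative_change`` alternative is (early - base) / base.
    """
    if not 0 <= early_phase < curve.signal.size:
        raise ValueError("early phase out of range")
    early = float(curve.signal[early_phase])
    base = curve.baseline
    if convention == "as_printed":
        if early <= 0:
            raise ValueError("non-positive early-phase signal")
        return base / early
    if convention == "relative_change":
        if base <= 0:
            raise ValueError("non-positive baseline")
        return (early - base) / base
    raise ValueError(f"unknown IER convention {convention!r}")


def compute_u_phases(
    curve: TimeSignalCurve,
    schedule: AcquisitionSchedule,
    threshold_frac: float = 0.10,
) -> tuple[int | None, int | None, float]:
    """(U1, U2, U2 time); U2 = U1 + 1 clamped to the last frame."""
    u1 = onset_phase(curve, threshold_frac)
    if u1 is None:
        return NO_ONSET, NO_ONSET, float("nan")
    u2 = u1 + 1
    if u2 >= schedule.n_frames:
        warnings.warn("onset at final frame; clamping U2 to the last frame")
        u2 = schedule.n_frames - 1
    return u1, u2, float(schedule.times[u2])


def cad_kinetics(
    standard: DceSeries,
    tumor_mask: np.ndarray,
    enh_threshold: float = 0.50,
    delta: float = 0.10,
) -> StandardKinetics:
    """CAD kinetic map summary on the standard series.

    Initial phase = first post-contrast frame, delayed phase = last frame.
    Voxels whose initial enhancement fraction exceeds ``enh_threshold`` are
    evaluated; their delayed-vs-initial change classifies them as washout
    (< -delta), persistent (> +delta) or plateau (boundaries inclusive).
    Percentages are over evaluated voxels; NaN when no voxel is evaluated.
    """
    mask = np.asarray(tumor_mask, dtype=bool)
    if not mask.any():
        raise ValueError("tumor mask is empty")
    n_pre = standard.schedule.n_precontrast
    if standard.data.shape[0] < n_pre + 2:
        raise ValueError("need at least two post-contrast frames")
    pre = standard.data[:n_pre].mean(axis=0)[mask]
    init = standard.data[n_pre][mask]
    delayed = standard.data[-1][mask]
    if np.any(pre <= 0):
        raise ValueError("non-positive precontrast signal inside the tumor mask")
    enh = (init - pre) / pre
    peak = 100.0 * float(np.max(enh))
    evaluated = enh > enh_threshold
    n_eval = int(evaluated.sum())
    if n_eval == 0:
        logger.warning("no voxel passes the %.0f%% threshold", 100 * enh_threshold)
        return StandardKinetics(peak, float("nan"), float("nan"), float("nan"))
    change = (delayed[evaluated] - init[evaluated]) / init[evaluated]
    washout = 100.0 * float(np.sum(change < -delta)) / n_eval
    persistent = 100.0 * float(np.sum(change > delta)) / n_eval
    plateau = 100.0 - washout - persistent
    return StandardKinetics(peak, washout, plateau, persistent)


def ultrafast_kinetics(
    ultrafast: DceSeries,
    tumor_mask: np.ndarray,
    aorta_mask: np.ndarray,
    cfg: KineticsConfig | None = None,
) -> UltrafastKinetics:
    """All four ultrafast descriptors from hotspot curves of one lesion."""
    cfg = cfg or KineticsConfig()
    t_roi = find_hotspot(ultrafast, tumor_mask, cfg.hotspot_diameter_mm)
    a_roi = find_hotspot(ultrafast, aorta_mask, cfg.hotspot_diameter_mm)
    t_curve = extract_curve(ultrafast, t_roi)
    a_curve = extract_curve(ultrafast, a_roi)
    tte = compute_tte(t_curve, a_curve, cfg.frame_interval_s, cfg.onset_threshold)
    slope = compute_max_slope(t_curve)
    u1, u2, u2_time = compute_u_phases(t_curve, ultrafast.schedule, cfg.onset_threshold)
    ier = float("nan") if u2 is None else compute_ier(t_curve, u2, cfg.ier_convention)
    return UltrafastKinetics(tte, slope, ier, u1, u2, u2_time)
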