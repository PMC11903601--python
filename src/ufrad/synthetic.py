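"""Digital DCE-MRI phantom cohorts with known kinetic ground truth.

Each lesion is a pair of co-registered dynamic series (ultrafast and
standard) on a common voxel grid holding three tissues: an ellipsoidal
tumor with a multiplicative heterogeneity field (texture), a cylindrical
arterial reference ("aorta") with early enhancement, and slowly enhancing
background parenchyma.  Every voxel follows a piecewise-linear
enhancement curve — baseline until an onset time, linear uptake to a peak,
then a linear late phase (washout / plateau / persistent) — plus additive
Gaussian noise.  Piecewise-linear curves keep all planted descriptors
(onset frame, slope, washout class) analytically checkable.

Class labels (hormone receptor, HER2, St. Gallen subtype) shift the
tumor's kinetic and texture parameters through an effect map, emulating
reported associations such as shorter time-to-enhancement in HER2-positive
cancers.  A ``modality_specific_effect`` fraction confines the class
signal to the ultrafast acquisition.  A perturbed "second reader" mask is
produced by flipping boundary voxels of the true mask.

All randomness flows from one integer seed through ``numpy``'s
``SeedSequence`` spawning, so identical specs yield identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ufrad.images import DceSeries, save_series, save_mask
from ufrad.kinetics import TimeSignalCurve
from ufrad.schedules import (
    AcquisitionSchedule,
    ultrafast_schedule,
    standard_schedule,
)

SUBTYPES = ("luminal", "her2_overexpressed", "triple_negative")


def subtype_label(hr: int, her2: int) -> str:
    """St. Gallen partition: luminal = HR+, HER2-overexpressed = HR-/HER2+,
    triple-negative = HR-/HER2-."""
    if hr:
        return "luminal"
    return "her2_overexpressed" if her2 else "triple_negative"


@dataclass(frozen=True)
class TissueKinetics:
    """Parameters of one tissue's piecewise-linear enhancement curve.

    baseline_si : precontrast signal (a.u., > 0)
    onset_s : enhancement onset after injection (s)
    uptake_slope : fractional relative enhancement per second during uptake
    peak_time_s : end of the uptake ramp (s, > onset_s)
    late_rate : fractional change of the peak signal per second afterwards
        (negative = washout, ~0 = plateau, positive = persistent)
    """

    baseline_si: float = 100.0
    onset_s: float = 12.6
    uptake_slope: float = 0.05
    peak_time_s: float = 46.2
    late_rate: float = -0.0005

    def __post_init__(self) -> None:
        if self.baseline_si <= 0:
            raise ValueError("baseline_si must be positive")
        if self.onset_s < 0 or self.uptake_slope < 0:
            raise ValueError("onset_s and uptake_slope must be non-negative")
        if self.peak_time_s <= self.onset_s:
            raise ValueError("peak_time_s must exceed onset_s")


def enhancement_curve(
    k: TissueKinetics, schedule: AcquisitionSchedule
) -> TimeSignalCurve:
    """Sample the piecewise-linear curve of ``k`` on a schedule.

    SI(t) = baseline for t <= onset; rises at ``uptake_slope x baseline``
    per second until ``peak_time_s``; then changes at ``late_rate x peak
    signal`` per second, floored at zero.
    """
    sig = _curve_values(k, schedule.times)
    return TimeSignalCurve(schedule.times, sig, schedule.n_precontrast)


def _curve_values(k: TissueKinetics, times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    rise = k.baseline_si * (1.0 + k.uptake_slope * (t - k.onset_s))
    peak = k.baseline_si * (1.0 + k.uptake_slope * (k.peak_time_s - k.onset_s))
    late = peak * (1.0 + k.late_rate * (t - k.peak_time_s))
    sig = np.where(t <= k.onset_s, k.baseline_si, np.where(t <= k.peak_time_s, rise, late))
    return np.maximum(sig, 0.0)


# --------------------------------------------------------------------------
# phantom geometry and generation

DEFAULT_TUMOR = TissueKinetics(100.0, 12.6, 0.05, 46.2, -0.0005)
DEFAULT_AORTA = TissueKinetics(120.0, 4.2, 0.15, 21.0, -0.001)
DEFAULT_BACKGROUND = TissueKinetics(80.0, 60.0, 0.005, 200.0, 0.0)


@dataclass
class PhantomSpec:
    """Geometry, kinetics and noise of one paired-series phantom.

    The grid is (slices, rows, cols); default 32 slices of 64 x 64 voxels
    at 1 mm isotropic spacing.  ``tumor_kinetics_standard`` lets the
    standard series follow different (e.g. class-independent) kinetics for
    modality-specific effects; None means both series share
    ``tumor_kinetics``.
    """

    grid_shape: tuple[int, int, int] = (32, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_center_mm: tuple[float, float, float] = (16.0, 22.0, 22.0)
    tumor_radii_mm: tuple[float, float, float] = (6.0, 8.0, 7.0)
    tumor_kinetics: TissueKinetics = field(default_factory=lambda: DEFAULT_TUMOR)
    tumor_kinetics_standard: TissueKinetics | None = None
    tumor_heterogeneity: float = 0.10
    tumor_heterogeneity_standard: float | None = None
    aorta_center_mm: tuple[float, float] = (50.0, 50.0)
    aorta_radius_mm: float = 4.0
    aorta_kinetics: TissueKinetics = field(default_factory=lambda: DEFAULT_AORTA)
    background_kinetics: TissueKinetics = field(
        default_factory=lambda: DEFAULT_BACKGROUND
    )
    noise_sd: float = 2.0
    reader2_flip_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.reader2_flip_fraction <= 0.5:
            raise ValueError("reader2_flip_fraction must lie in [0, 0.5]")


@dataclass
class LesionRecord:
    """One simulated lesion: both series, masks, labels and planted truth."""

    lesion_id: str
    ultrafast: DceSeries
    standard: DceSeries
    tumor_mask: np.ndarray
    aorta_mask: np.ndarray
    reader2_mask: np.ndarray
    labels: dict[str, object]
    truth: TissueKinetics


def _ellipsoid_mask(grid_shape, spacing_mm, center_mm, radii_mm) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(grid_shape, spacing_mm)], indexing="ij"
    )
    return (
        ((zz - center_mm[0]) / radii_mm[0]) ** 2
        + ((yy - center_mm[1]) / radii_mm[1]) ** 2
        + ((xx - center_mm[2]) / radii_mm[2]) ** 2
    ) <= 1.0


def _cylinder_mask(grid_shape, spacing_mm, center_yx_mm, radius_mm) -> np.ndarray:
    yy, xx = np.meshgrid(
        np.arange(grid_shape[1]) * spacing_mm[1],
        np.arange(grid_shape[2]) * spacing_mm[2],
        indexing="ij",
    )
    disc = ((yy - center_yx_mm[0]) ** 2 + (xx - center_yx_mm[1]) ** 2) <= radius_mm**2
    return np.broadcast_to(disc, grid_shape).copy()


def _smooth_unit_field(shape, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean unit-SD Gaussian field (spatial texture driver)."""
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=2.0)
    return (smooth - smooth.mean()) / max(smooth.std(), 1e-12)


def _render_series(
    schedule: AcquisitionSchedule,
    spec: PhantomSpec,
    tumor_kin: TissueKinetics,
    masks: tuple[np.ndarray, np.ndarray],
    het: np.ndarray,
    rng: np.random.Generator,
) -> DceSeries:
    tumor, aorta = masks
    t_curve = _curve_values(tumor_kin, schedule.times)
    a_curve = _curve_values(spec.aorta_kinetics, schedule.times)
    b_curve = _curve_values(spec.background_kinetics, schedule.times)
    n_t = schedule.n_frames
    data = np.empty((n_t,) + spec.grid_shape)
    for i in range(n_t):
        frame = np.full(spec.grid_shape, b_curve[i])
        frame[tumor] = t_curve[i] * het[tumor]
        frame[aorta] = a_curve[i]
        data[i] = frame
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    return DceSeries(data, spec.spacing_mm, schedule)


def generate_phantom(spec: PhantomSpec) -> LesionRecord:
    """Render one paired ultrafast/standard phantom, deterministic in ``seed``."""
    tumor = _ellipsoid_mask(
        spec.grid_shape, spec.spacing_mm, spec.tumor_center_mm, spec.tumor_radii_mm
    )
    aorta = _cylinder_mask(
        spec.grid_shape, spec.spacing_mm, spec.aorta_center_mm, spec.aorta_radius_mm
    )
    if not tumor.any() or not aorta.any():
        raise ValueError("tumor or aorta geometry lies outside the grid")
    if (tumor & aorta).any():
        raise ValueError("tumor and aorta masks overlap")

    ss = np.random.SeedSequence(spec.seed)
    rng_het, rng_uf, rng_std, rng_r2 = [np.random.default_rng(s) for s in ss.spawn(4)]
    # one spatial texture field, possibly different amplitude per modality
    base_field = _smooth_unit_field(spec.grid_shape, rng_het)
    het_uf = np.exp(spec.tumor_heterogeneity * base_field)
    level_std = (
        spec.tumor_heterogeneity
        if spec.tumor_heterogeneity_standard is None
        else spec.tumor_heterogeneity_standard
    )
    het_std = np.exp(level_std * base_field)

    uf = _render_series(
        ultrafast_schedule(), spec, spec.tumor_kinetics, (tumor, aorta), het_uf, rng_uf
    )
    std_kin = spec.tumor_kinetics_standard or spec.tumor_kinetics
    std = _render_series(
        standard_schedule(), spec, std_kin, (tumor, aorta), het_std, rng_std
    )
    reader2 = perturb_mask(
        tumor, spec.reader2_flip_fraction, rng=rng_r2
    )
    return LesionRecord(
        lesion_id=f"lesion_{spec.seed}",
        ultrafast=uf,
        standard=std,
        tumor_mask=tumor,
        aorta_mask=aorta,
        reader2_mask=reader2,
        labels={},
        truth=spec.tumor_kinetics,
    )


def perturb_mask(
    mask: np.ndarray,
    boundary_flip_fraction: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulated second-reader mask: flip a fraction of boundary voxels.

    Candidates are mask voxels on the inner boundary (erosion residue) and
    background voxels on the outer boundary (dilation residue); a
    ``boundary_flip_fraction`` of each set, drawn without replacement, is
    flipped.  A single-voxel mask is returned unchanged (no boundary to
    erode safely); the result is always non-empty.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("input mask is empty")
    if not 0 <= boundary_flip_fraction <= 0.5:
        raise ValueError("boundary_flip_fraction must lie in [0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = mask.copy()
    if boundary_flip_fraction == 0 or mask.sum() == 1:
        return out
    inner = mask & ~ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) & ~mask
    for cand, value in ((inner, False), (outer, True)):
        idx = np.flatnonzero(cand)
        n_flip = int(np.floor(boundary_flip_fraction * idx.size))
        if n_flip == 0:
            continue
        chosen = rng.choice(idx, size=n_flip, replace=False)
        out.flat[chosen] = value
    if not out.any():  # pathological tiny mask: keep one voxel
        out.flat[np.flatnonzero(mask)[0]] = True
    return out


# --------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class KineticEffect:
    """Shift applied to the tumor kinetics/texture when a label is positive."""

    onset_shift_s: float = 0.0
    slope_scale: float = 1.0
    late_rate_shift: float = 0.0
    heterogeneity_shift: float = 0.0

    def scaled(self, frac: float) -> "KineticEffect":
        return KineticEffect(
            self.onset_shift_s * frac,
            1.0 + (self.slope_scale - 1.0) * frac,
            self.late_rate_shift * frac,
            self.heterogeneity_shift * frac,
        )


#: Default class effects: HER2-positive tumors enhance earlier and steeper
#: with more heterogeneous texture; hormone-receptor-positive tumors enhance
#: later and less steeply.
DEFAULT_EFFECTS: dict[str, KineticEffect] = {
    "HER2": KineticEffect(onset_shift_s=-8.4, slope_scale=1.4, heterogeneity_shift=0.05),
    "HR": KineticEffect(onset_shift_s=4.2, slope_scale=0.85),
}


@dataclass
class CohortSpec:
    """Cohort-level simulation parameters.

    Label priors default to the class structure of the emulated study
    population (80% hormone-receptor positive, 22% HER2 positive).
    ``modality_specific_effect`` in [0, 1] is the fraction of each class
    effect expressed only in the ultrafast series (1.0 = the standard
    series carries no class signal).  Per-lesion biological variability
    jitters onset, slope and baseline around the class means.
    """

    n_lesions: int = 40
    hr_prior: float = 0.80
    her2_prior: float = 0.22
    effects: dict[str, KineticEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    modality_specific_effect: float = 0.0
    base_tumor: TissueKinetics = field(default_factory=lambda: DEFAULT_TUMOR)
    onset_jitter_s: float = 2.1
    slope_jitter_sd: float = 0.15
    baseline_jitter_sd: float = 0.05
    grid_shape: tuple[int, int, int] = (32, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 2.0
    reader2_flip_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.hr_prior, self.her2_prior):
            if not 0 <= p <= 1:
                raise ValueError("priors must lie in [0, 1]")
        if self.hr_prior == 0 and self.her2_prior == 0 and self.n_lesions == 0:
            raise ValueError("degenerate cohort")
        if not 0 <= self.modality_specific_effect <= 1:
            raise ValueError("modality_specific_effect must lie in [0, 1]")


def _apply_effect(
    k: TissueKinetics, eff: KineticEffect, het: float
) -> tuple[TissueKinetics, float]:
    onset = max(0.0, k.onset_s + eff.onset_shift_s)
    return (
        replace(
            k,
            onset_s=onset,
            uptake_slope=k.uptake_slope * eff.slope_scale,
            late_rate=k.late_rate + eff.late_rate_shift,
            peak_time_s=max(k.peak_time_s, onset + 8.4),
        ),
        het + eff.heterogeneity_shift,
    )


def _combined_effect(labels: dict, effects: dict[str, KineticEffect]) -> KineticEffect:
    onset, slope, late, het = 0.0, 1.0, 0.0, 0.0
    for name, eff in effects.items():
        if labels.get(name, 0):
            onset += eff.onset_shift_s
            slope *= eff.slope_scale
            late += eff.late_rate_shift
            het += eff.heterogeneity_shift
    return KineticEffect(onset, slope, late, het)


def generate_cohort(cspec: CohortSpec) -> list[LesionRecord]:
    """Draw labels from the priors and render one phantom per lesion."""
    if cspec.n_lesions < 2:
        raise ValueError("need at least 2 lesions")
    ss = np.random.SeedSequence(cspec.seed)
    rng_labels = np.random.default_rng(ss.spawn(1)[0])
    lesion_seeds = np.random.SeedSequence(cspec.seed + 1).generate_state(
        cspec.n_lesions
    ) % (2**31 - 1)

    hr = rng_labels.random(cspec.n_lesions) < cspec.hr_prior
    her2 = rng_labels.random(cspec.n_lesions) < cspec.her2_prior
    records = []
    for i in range(cspec.n_lesions):
        labels = {
            "HR": int(hr[i]),
            "HER2": int(her2[i]),
            "subtype": subtype_label(int(hr[i]), int(her2[i])),
        }
        rng_i = np.random.default_rng(int(lesion_seeds[i]))
        base = replace(
            cspec.base_tumor,
            baseline_si=cspec.base_tumor.baseline_si
            * float(np.exp(cspec.baseline_jitter_sd * rng_i.standard_normal())),
            onset_s=max(
                0.0,
                cspec.base_tumor.onset_s
                + float(rng_i.uniform(-cspec.onset_jitter_s, cspec.onset_jitter_s)),
            ),
            uptake_slope=cspec.base_tumor.uptake_slope
            * float(np.exp(cspec.slope_jitter_sd * rng_i.standard_normal())),
        )
        eff = _combined_effect(labels, cspec.effects)
        uf_kin, uf_het = _apply_effect(base, eff, 0.10)
        std_kin, std_het = _apply_effect(
            base, eff.scaled(1.0 - cspec.modality_specific_effect), 0.10
        )
        spec = PhantomSpec(
            grid_shape=cspec.grid_shape,
            spacing_mm=cspec.spacing_mm,
            tumor_kinetics=uf_kin,
            tumor_kinetics_standard=std_kin,
            tumor_heterogeneity=max(0.0, uf_het),
            tumor_heterogeneity_standard=max(0.0, std_het),
            noise_sd=cspec.noise_sd,
            reader2_flip_fraction=cspec.reader2_flip_fraction,
            seed=int(lesion_seeds[i]),
        )
        if cspec.grid_shape != PhantomSpec.grid_shape:
            spec = _rescale_geometry(spec)
        rec = generate_phantom(spec)
        rec.lesion_id = f"lesion_{i:04d}"
        rec.labels = labels
        records.append(rec)
    return records


def _rescale_geometry(spec: PhantomSpec) -> PhantomSpec:
    """Scale default tumor/aorta geometry to a non-default grid."""
    fz = spec.grid_shape[0] / 32.0
    fy = spec.grid_shape[1] / 64.0
    fx = spec.grid_shape[2] / 64.0
    spec.tumor_center_mm = (16.0 * fz, 22.0 * fy, 22.0 * fx)
    spec.tumor_radii_mm = (6.0 * fz, 8.0 * fy, 7.0 * fx)
    spec.aorta_center_mm = (50.0 * fy, 50.0 * fx)
    spec.aorta_radius_mm = max(1.6, 4.0 * min(fy, fx))
    return spec


def scenario_s1(
    n_lesions: int = 200,
    n_predictors: int = 100,
    n_informative: int = 7,
    effect_size: float = 1.5,
    positive_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Preset feature-level scenario "S1": a flat feature table.

    A fixed subset of ``n_informative`` predictors (named ``info_00``...)
    carries a standardized between-class mean shift of ``effect_size``;
    the remaining predictors (``noise_*``) are independent standard
    Gaussian noise.  Returns a DataFrame with a binary ``label`` column.
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(positive_fraction * n_lesions))
    y = np.zeros(n_lesions, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    X = rng.standard_normal((n_lesions, n_predictors))
    X[:, :n_informative] += effect_size * y[:, None]
    names = [f"info_{i:02d}" for i in range(n_informative)] + [
        f"noise_{i:03d}" for i in range(n_predictors - n_informative)
    ]
    df = pd.DataFrame(X, columns=names)
    df["label"] = y
    return df


# --------------------------------------------------------------------------
# on-disk cohort layout

def write_cohort(
    records: list[LesionRecord], outdir: str | Path, cspec: CohortSpec | None = None
) -> Path:
    """Write per-lesion NIfTI files plus a manifest CSV and spec JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        base = outdir / rec.lesion_id
        save_series(rec.ultrafast, f"{base}_ultrafast.nii.gz")
        save_series(rec.standard, f"{base}_standard.nii.gz")
        sp = rec.ultrafast.spacing_mm
        save_mask(rec.tumor_mask, sp, f"{base}_tumor_mask.nii.gz")
        save_mask(rec.aorta_mask, sp, f"{base}_aorta_mask.nii.gz")
        save_mask(rec.reader2_mask, sp, f"{base}_reader2_mask.nii.gz")
        rows.append(
            {
                "lesion_id": rec.lesion_id,
                "HR": rec.labels.get("HR"),
                "HER2": rec.labels.get("HER2"),
                "subtype": rec.labels.get("subtype"),
                "ultrafast": f"{rec.lesion_id}_ultrafast.nii.gz",
                "standard": f"{rec.lesion_id}_standard.nii.gz",
                "tumor_mask": f"{rec.lesion_id}_tumor_mask.nii.gz",
                "aorta_mask": f"{rec.lesion_id}_aorta_mask.nii.gz",
                "reader2_mask": f"{rec.lesion_id}_reader2_mask.nii.gz",
            }
        )
    manifest = outdir / "cohort_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if cspec is not None:
        spec_dict = asdict(cspec)
        spec_dict["effects"] = {k: asdict(v) for k, v in cspec.effects.items()}
        (outdir / "cohort_spec.json").write_text(json.dumps(spec_dict, indent=2))
    return manifest


def load_cohort(outdir: str | Path) -> list[LesionRecord]:
    """Re-read a cohort written by :func:`write_cohort`."""
    from ufrad.images import load_series, load_mask

    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "cohort_manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        uf = load_series(outdir / row["ultrafast"], ultrafast_schedule())
        std = load_series(outdir / row["standard"], standard_schedule())
        tumor, _ = load_mask(outdir / row["tumor_mask"])
        aorta, _ = load_mask(outdir / row["aorta_mask"])
        reader2, _ = load_mask(outdir / row["reader2_mask"])
        records.append(
            LesionRecord(
                lesion_id=row["lesion_id"],
                ultrafast=uf,
                standard=std,
                tumor_mask=tumor,
                aorta_mask=aorta,
                reader2_mask=reader2,
                labels={
                    "HR": int(row["HR"]),
                    "HER2": int(row["HER2"]),
                    "subtype": row["subtype"],
                },
                truth=DEFAULT_TUMOR,
            )
        )
    return records
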