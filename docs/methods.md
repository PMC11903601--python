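# Methods

This note documents the models, numerical choices and limitations of
`ufrad`. It is written for a maintainer deciding whether a result on the
synthetic cohorts transfers to real imaging data.

## Enhancement model and the phantom

Each tissue follows a piecewise-linear time–signal curve

    SI(t) = B                                    t ≤ t0
    SI(t) = B · (1 + s · (t − t0))               t0 < t ≤ tp
    SI(t) = SI(tp) · (1 + r · (t − tp))          t > tp      (floored at 0)

with baseline `B` (a.u.), onset `t0` (s), fractional uptake slope `s`
(1/s), peak time `tp` and late rate `r` (1/s; negative = washout, ≈0 =
plateau, positive = persistent). A linear-segment model — rather than a
pharmacokinetic (Tofts-type) model — was chosen because the measured
descriptors are empirical curve features (onset frame, steepest segment,
delayed-phase change), and linear segments make every planted value
analytically recoverable: the expected onset frame is the first frame past
`t0 + threshold/s`, the discrete maximum slope equals `100·s` %/s exactly
whenever at least one frame interval lies fully inside the rise.

The phantom grid defaults to 32 slices of 64×64 voxels at 1 mm isotropic
spacing — large enough for 3 mm ROIs and texture statistics, small enough
that a full feature extraction takes ~0.2 s. It holds three tissues:

- **tumor**: ellipsoid (default radii 6/8/7 mm), baseline 100 a.u., onset
  12.6 s, uptake 0.05/s, peak 46.2 s, late rate −5·10⁻⁴/s (≈12% decline
  over the standard delayed window, i.e. washout);
- **aorta**: a cylinder along the slice axis with early enhancement
  (onset 4.2 s, uptake 0.15/s). Anatomical realism is not attempted; the
  pipeline only needs a reference structure that enhances before the tumor;
- **background parenchyma**: slow late enhancement (onset 60 s, 0.005/s).
  No quantitative description of background parenchymal enhancement
  dynamics was available, so it is modeled as a slow-onset tissue curve
  with configurable amplitude; its main role is to make hotspot search and
  mask dilation non-trivial.

Tumor voxels are multiplied by a smooth log-normal heterogeneity field
(Gaussian-filtered white noise, σ = 2 voxels, log-SD 0.10 by default) —
this is what gives the lesion texture. Additive Gaussian noise (default
SD 2 a.u. = 2% of tumor baseline) is applied to every frame. All
randomness derives from a single integer seed through `SeedSequence`
spawning; identical specs produce bit-identical cohorts.

**Class effects.** Cohort labels are drawn independently (defaults: 80%
HR-positive, 22% HER2-positive, matching a typical clinical case mix);
subtype is the deterministic St. Gallen partition. Positive labels shift
the tumor kinetics: HER2+ advances onset by 8.4 s (two ultrafast frames),
scales uptake ×1.4 and adds 0.05 heterogeneity; HR+ delays onset by 4.2 s
and scales uptake ×0.85 — directions follow the reported association of
shorter time-to-enhancement with HER2 positivity and HR negativity; the
magnitudes are package choices giving realistic (strong but not trivial)
class separation against the per-lesion jitter (onset ±2.1 s uniform,
slope log-SD 0.15, baseline log-SD 0.05). `modality_specific_effect` m ∈
[0, 1] expresses only a fraction (1 − m) of the effect (kinetics *and*
heterogeneity) in the standard series; at m = 1 the standard series is
class-independent by construction.

**Second reader.** The simulated second-reader mask flips a fraction of
inner- and outer-boundary voxels (erosion/dilation residues) of the true
mask. Boundary flips rather than global deformation keep the expected
Dice analytically controllable; the default fraction 0.25 yields Dice
≈ 0.91 on the default tumor, matching reported two-reader agreement.
A single-voxel mask is returned unchanged (there is no boundary that can
be flipped without emptying it).

**Scenario S1** bypasses imaging entirely: a flat feature table with
`n_informative` (default 7) predictors carrying a standardized
between-class mean shift of 1.5 (within-class SD 1) among independent
Gaussian noise columns. It is the reference condition for testing whether
the selection procedure retrieves a known predictor set.

## Kinetic extraction

The hotspot ROI is the in-plane 3 mm disc (voxel centers within the
radius), centered on a tumor voxel, maximizing mean relative enhancement
`(SI_last − SI_pre)/SI_pre` on the last ultrafast frame; ties break toward
the lowest (slice, row, col) index, and a tumor smaller than the disc
shrinks the ROI to the available voxels with a warning. The same machinery
with the aorta mask provides the arterial reference curve.

- **Onset (U1)**: first post-contrast frame strictly above 1.1× the
  precontrast mean. The same 10% rule is applied to the aorta (the source
  protocol states the rule for the tumor only).
- **TTE** = (tumor onset phase − aorta onset phase) × `frame_interval_s`.
  The frame interval defaults to 4.2 s: interpreting the multiplier as the
  pulse-sequence repetition time (~4 ms) would produce millisecond TTEs,
  inconsistent with TTE being reported in seconds.
- **Maximum slope**: maximum over consecutive frame pairs of
  Δ(relative enhancement %)/Δt. Computed on relative enhancement, not raw
  signal, because the descriptor's units are %/s.
- **IER**: by default the printed convention, precontrast mean ÷ early
  signal (∈ (0, 1] for enhancing curves); a `relative_change` switch
  computes (early − base)/base instead. The "early phase" defaults to U2,
  the established tumor measurement time.
- **CAD kinetics** on the standard series: initial phase = first
  post-contrast frame (58.8 s), delayed phase = last frame (298.8 s).
  Voxels with initial enhancement > 50% are evaluated; delayed-vs-initial
  change < −10% = washout, > +10% = persistent, boundaries inclusive =
  plateau. Percentages are over evaluated voxels (they always sum to 100
  when any voxel is evaluated; otherwise they are NaN and peak enhancement
  is still reported).

**Known estimator bias.** The maximum over ~7 noisy rise segments is
upward-biased: with per-frame noise at 2% of baseline the mean relative
slope error is ≈7–10% (it scales linearly with the noise and shrinks with
steeper planted slopes). Onset recovery is unaffected (the 10% threshold
is ≈5σ above disc-mean noise at 2%). The round-trip validation therefore
asserts onset recovery at 2% noise and slope recovery (within 10%) at 1%
noise, and the acceptance script reports the slope error at both levels.

## Radiomic features

Pipeline: whole-volume z-score normalization → isotropic resampling to
1 mm (trilinear image, nearest-neighbor mask) → bounding-box crop (8-voxel
pad) → feature groups. The manifest is fixed at 17 first-order, 7 shape,
162 texture and 1432 wavelet features (1618 total); the counts are the
contract, the descriptor composition is a package choice, versioned in
code (`MANIFEST_VERSION`) and exported as JSON beside every feature table.

- **First-order (17)**: mean, median, min, max, range, variance, SD
  (population convention), skewness, excess kurtosis (both 0 for constant
  regions), energy, total energy (× voxel volume), entropy and uniformity
  (on the discretized histogram), mean absolute deviation, RMS, 10th/90th
  percentiles.
- **Shape (7)**: voxel volume; mesh surface area (marching cubes on a
  σ = 1 voxel Gaussian-smoothed mask — smoothing removes the voxel
  staircase, whose area excess does not vanish with resolution; tiny masks
  whose smoothed field stays below the 0.5 level fall back to the binary
  surface); surface-to-volume ratio; sphericity π^⅓(6V)^⅔/A; maximum 3D
  diameter (max pairwise distance of voxel centers, via the convex hull
  for large masks); major axis length 4√λ₁ and elongation √(λ₁/λ₂) from
  the voxel-coordinate covariance eigenvalues, regularized by the moment
  of a single voxel (spacing²/12) so rods and single voxels stay finite
  (elongation ≈ 1 for a cube, ≫ 1 for a rod).
- **Texture (162)**: intensities are discretized to a fixed bin count
  (default 32) over the in-mask range. Symmetric GLCMs at distance 1 for
  the four in-plane offsets (0°, 45°, 90°, 135°); 22 descriptors per
  offset plus once more on the direction-averaged matrix (110), and 13
  GLRLM descriptors per offset (52). Runs break at mask boundaries.
  Degenerate limits are defined (constant region: GLCM energy 1, contrast
  0, correlation 1).
- **Wavelet (1432)**: one-level stationary (undecimated) 3D transform,
  coif1 by default (compactly supported, orthogonal; recorded in the
  config), sub-bands ordered LLL…HHH with one L/H letter per axis. Being
  undecimated, sub-bands keep the original grid, so the mask applies
  directly and features are shift-invariant. Odd axes are edge-padded to
  even length and cropped back. On each sub-band the 17 first-order + 162
  texture features are recomputed.

Features computed per (lesion, modality, mask source): the ultrafast
frame is the lesion's U2 phase, the standard frame is the first
post-contrast frame; masks come from the reference segmentation or the
simulated second reader.

## Selection and classification

Features (radiomic + kinetic together) are z-scored column-wise
(population SD; constant columns dropped, missing values median-imputed).
For each of 25 repeats, the fold assignment of a stratified five-fold
split is reshuffled (seeded) and an L1-penalized logistic regression is
fitted per training fold at fixed λ = 0.05 (liblinear, C = 1/(n·λ),
matching the per-observation penalty convention). A predictor counts as
*selected in the repeat* when its coefficient is nonzero in **every** fold
fit — the all-folds rule is the stricter reading of "selected by the
cross-validated fit" and measurably cuts spurious stability on noise
(false inclusion 1.3% vs ~6% with fold-average counting).

Predictors selected in ≥ 20 of 25 repeats survive the count filter. The
0.6 magnitude threshold is then applied to the coefficients of a single
**relaxed post-selection logistic refit** on the survivors (unit ridge for
identifiability under near-separation) rather than to raw LASSO
coefficients: at fixed λ the L1 budget caps the total coefficient mass
(Σ|w| ≈ 3.5 at λ = 0.05) regardless of effect size, so several predictors
sharing a strong signal can never all clear an absolute 0.6 on shrunken
coefficients — the relaxed-refit coefficients are the consistent scale for
an absolute threshold. Survivors are ranked by (count, |refit
coefficient|) and truncated to the top 7 (`max_features`, configurable:
on other data the thresholds alone may yield a different count).

The final model is a maximum-likelihood logistic regression on the
selected predictors with per-sample weights N/(2·N_class) (inverse class
frequency). Standard errors come from the GLM information matrix;
complete separation (detected by exploding standard errors) triggers a
lightly L2-penalized fallback, flagged in the results. An empty selection
is a valid outcome; the task runner then fits the weighted model on all
predictors (logged) so a score is always defined.

Evaluation scores are **out-of-fold**: stability selection runs once on
the full table (mirroring the reference protocol), then repeated seeded
stratified cross-validation refits only the weighted logistic per training
fold and scores the held-out fold. Full-table selection is mildly
optimistic relative to nested selection, but keeps the protocol faithful
to the emulated study while avoiding resubstitution optimism in the
classifier itself; the paired ultrafast-vs-standard comparisons apply the
same protocol to both arms, so the comparison is fair. λ is fixed at 0.05
by default (the reported operating point); a CV-over-grid mode is
available via `StabilityConfig`.

## Statistics

- **AUC**: Mann–Whitney with 0.5 tie credit (scikit-learn); verified in
  tests against exhaustive pair counting.
- **Confidence intervals**: medians and 2.5/97.5 percentiles of the metric
  over repeated-CV replicate score sets (or bootstrap resamples when no
  replicates exist). How the emulated study computed its CIs is not
  stated; percentile intervals over replicates are the package's choice.
- **Threshold metrics**: accuracy/sensitivity/specificity at probability
  0.5 on the class-weighted model by default (a Youden-optimal threshold
  is a one-line change on the caller side).
- **DeLong test**: placement-value (midrank) covariance estimator for
  paired AUCs, two-sided normal p-value; p = 1 when the variance of the
  difference is zero and the AUCs are equal (e.g. identical score
  vectors). Verified against a direct ψ-kernel covariance assembly and
  calibrated to ~5% type-I error on paired null scores.
- **Overlap**: Dice 2|A∩B|/(|A|+|B|), Jaccard |A∩B|/|A∪B| (NaN for two
  empty masks); the identity J = D/(2−D) is property-tested.
- **Correlation maps**: Pearson r per (predictor, binary label); constant
  predictors get r = 0 and are flagged.

## Problem sizes used in validation

The shipped tests and `scripts/acceptance.py` run on desk-scale problems:
20 seeded phantoms for kinetic round-trips, 20 seeds × n = 200 for S1
recovery, 100 pure-noise replicates (n = 100, p = 30) for false inclusion,
1000 paired-null replicates for DeLong calibration, and n = 300 lesions on
a quarter-size grid (12×24×24) with kinetic features for the
modality-effect experiment. The full-size default grid with all 1622
features runs in the pipeline smoke tests at smaller n.

## Limitations

- No MR physics: no coil profiles, k-space sharing, SENSE artifacts, or
  rician noise floors; noise is additive Gaussian. Non-mass enhancement
  and diffuse lesion morphologies are not simulated.
- The piecewise-linear curve family cannot express early rim/washin
  heterogeneity within a lesion beyond the multiplicative texture field.
- Passing recovery and modality-effect tests shows the *pipeline* is
  correct and well calibrated under known ground truth; it does not
  certify classification performance on clinical data, where effect sizes,
  confounding and segmentation variability are unknown.
- The radiomic descriptor composition follows common IBSI-style
  definitions but is not claimed to numerically match any specific
  third-party extractor.
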