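# ufrad — ultrafast vs standard breast DCE-MRI radiomics

`ufrad` is a reusable, fully tested pipeline for comparing **ultrafast**
dynamic contrast-enhanced breast MRI (a precontrast frame plus 14
post-contrast frames at 4.2 s temporal resolution) against **standard**
DCE-MRI (post-contrast frames at 58.8/138.8/218.8/298.8 s) for classifying
breast-cancer histological factors — hormone-receptor (HR) status, HER2
status and the St. Gallen molecular subtypes (luminal, HER2-overexpressed,
triple-negative).

Because clinical DCE-MRI cohorts are rarely shareable, the package ships a
first-class **digital phantom generator**: paired 4D series per lesion with
piecewise-linear tissue enhancement curves (analytically checkable ground
truth), class-dependent kinetic/texture effects, background parenchymal
enhancement, additive noise and a simulated second-reader segmentation.
Every downstream stage is testable end to end without any download.

## What it computes

- **Ultrafast kinetics** from a 3 mm hotspot ROI: time to enhancement
  (TTE = (tumor onset phase − aorta onset phase) × 4.2 s), maximum slope
  (steepest consecutive-frame segment of the relative-enhancement curve,
  %/s), initial enhancement rate (IER), and the U1/U2 phases (U1 = first
  frame > 10% above the precontrast mean; U2 = the next frame).
- **Standard CAD kinetics**: per-voxel classification of the delayed-phase
  change among voxels enhancing > 50% initially — washout (< −10%),
  plateau (±10%), persistent (> +10%) — plus peak enhancement.
- **1618 radiomic features** per lesion and modality: 17 first-order, 7
  shape, 162 texture (GLCM per in-plane offset + direction-averaged, GLRLM
  per offset) and 1432 wavelet features (8 stationary-transform sub-bands ×
  (17 + 162)), after whole-volume z-score normalization and isotropic
  resampling. Kinetic features are appended, giving 1622 predictors.
- **Stability-LASSO selection + class-weighted logistic models**:
  L1-penalized logistic fits (λ = 0.05) over 25 reshuffled five-fold
  splits; predictors kept in ≥ 20 repeats and with |standardized
  coefficient| ≥ 0.6 in a relaxed post-selection refit, truncated to the
  top 7, then a logistic model with inverse-frequency class weights
  N/(2·N_class).
- **Evaluation**: AUC with 95% percentile CIs over repeated-CV replicates,
  accuracy/sensitivity/specificity, the paired DeLong test
  (placement-value covariance), Dice/Jaccard segmentation agreement, and
  Pearson feature–label correlation maps.

## Worked example

Kinetics of a default phantom (tumor onset 12.6 s, uptake 0.05/s, aorta
onset 4.2 s, 2% noise):

```python
from ufrad import PhantomSpec, generate_phantom, ultrafast_kinetics, cad_kinetics

rec = generate_phantom(PhantomSpec(seed=1))
uf = ultrafast_kinetics(rec.ultrafast, rec.tumor_mask, rec.aorta_mask)
std = cad_kinetics(rec.standard, rec.tumor_mask)
print(f"TTE            : {uf.tte_s:.1f} s   (U1 frame {uf.u1_phase}, U2 at {uf.u2_time_s:.1f} s)")
print(f"maximum slope  : {uf.max_slope_pct_per_s:.2f} %/s")
print(f"IER            : {uf.initial_enhancement_rate:.3f}")
print(f"peak enhancement {std.peak_enhancement_pct:.0f} %; washout/plateau/persistent "
      f"{std.washout_pct:.1f}/{std.plateau_pct:.1f}/{std.persistent_pct:.1f} %")
```

```
TTE            : 8.4 s   (U1 frame 4, U2 at 21.0 s)
maximum slope  : 5.52 %/s
IER            : 0.686
peak enhancement 183 %; washout/plateau/persistent 98.0/2.0/0.0 %
```

The tumor crosses the 10% enhancement threshold two frames after the aorta
(TTE = 2 × 4.2 s); the measured maximum slope (5.52 %/s) sits close to the
planted 5 %/s; 98% of evaluated tumor voxels show washout, as planted
(late rate −0.05 %/s of peak).

Fitting the classification model on the feature-level scenario "S1"
(seven planted predictors with standardized effect 1.5 among 93 noise
columns, n = 200):

```python
from ufrad import StabilityLogit, StabilityConfig
from ufrad.synthetic import scenario_s1

df = scenario_s1(n_lesions=200, seed=0)
model = StabilityLogit.from_dataframe(df, label_col="label",
                                      config=StabilityConfig(seed=0))
print(model.fit().summary())
```

```
Stability-LASSO weighted logistic regression
============================================================
n obs: 200   positives: 100   lambda: 0.05   repeats: 25
class weights: 0: 1.000, 1: 1.000
selected 7 predictors [L2 fallback: separation detected]
------------------------------------------------------------
predictor                              coef      se count
intercept                             0.913      --    --
info_03                              14.258      --    25
info_02                              13.928      --    25
info_06                               9.944      --    25
info_04                               8.509      --    25
info_00                               7.398      --    25
info_01                              10.060      --    25
info_05                               7.224      --    25
============================================================
```

All seven planted predictors are recovered with selection count 25/25; the
final logistic hits complete separation (the planted effect is strong), so
the lightly penalized fallback supplies the coefficients.

## Command line

```bash
ufrad run-all --config experiment.json --seed 1 --out results/
```

runs generate → extract → model → evaluate and writes NIfTI volumes, the
cohort manifest CSV, per-modality feature tables, per-task JSONs, and a
`report.json` with per-task performance, paired ultrafast-vs-standard
DeLong comparisons and segmentation-agreement summaries. `generate`,
`extract`, `model` and `evaluate` run individual stages from the artifacts
of the previous one.

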