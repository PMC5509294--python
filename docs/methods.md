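# Methods

## Model and procedure

The pipeline classifies spatially aligned FDG-PET volumes into a
disease and a healthy profile in two stages.

Stage 1 is mass-univariate: after preprocessing, each voxel is fitted
independently by OLS with design columns (healthy indicator, centered
age, intercept).  The t statistic for the contrast healthy − disease is
t = c᷀β̂ / √(σ̂² c᷀(X᷀X)⁻¹c), σ̂² = RSS/df, df = n − rank(X).  The
one-sided p = P(T_df > t) keeps only the hypometabolic direction
(disease uptake lower); the equivalent normal quantile z = Φ⁻¹(1 − p)
is stored for the weight-vs-z analysis.  Voxels with p < 0.005
(strict inequality) form connected components under 18-connectivity
(faces + edges; 6 and 26 are available behind a flag), and components
with K ≥ 200 voxels (inclusive) survive.  The retained clusters are
relabeled in descending-size order and reported with peak t and peak mm
coordinate.  No correction beyond cluster extent is applied — the
procedure deliberately stops at the voxel threshold plus extent filter,
without FWE/FDR.

Stage 2 trains a soft-margin linear SVM (hinge loss, L2 penalty) on the
masked intensities of the training subjects, disease coded +1, solved
through the convex dual (libsvm via scikit-learn) to tolerance 1e-6 —
deterministic for a given feature matrix.  Held-out subjects are scored
by s = w·x + b; s ≥ 0 classifies as disease (the measure-zero s = 0 tie
resolves toward sensitivity, and the convention is logged).  Evaluation
reports the confusion matrix (disease positive), Se/Sp/PPV/NPV/Acc, and
a Mann-Whitney U comparison of the decision scores.

## Assumptions

- Scans are already in a common template space with isotropic voxels
  (default 2 mm); registration is upstream and out of scope.
- Group-level hypometabolism is regional and consistent in sign; only
  decreased uptake enters the mask (one contrast direction).
- Age affects intensity approximately linearly over the adult range and
  identically in both groups (parallel-slopes ANCOVA).
- Global uptake differences between subjects are multiplicative and
  removable by proportional scaling.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `fwhm_mm` | 8 | mm | conventional PET smoothing kernel |
| `target_mean` | 50 | intensity | common global-scaling target of this software lineage |
| `p_voxel` | 0.005 | — | voxel-level screening threshold (strict `<`) |
| `k_min` | 200 | voxels | extent filter (inclusive `>=`) |
| `connectivity` | 18 | — | faces+edges components, the lineage's convention |
| `C` | 1.0 | — | SVM regularization; the solver default, configurable |
| baseline | 100 | intensity | phantom uptake level; effects are fractions of it |
| `noise_sd` | 10 | intensity | 10% of baseline, a realistic voxel-noise regime |
| `global_scale_sd` | 0.05 | — | 5% per-subject global uptake variation |
| `age_slope` | −0.15 | intensity/yr | mild metabolic decline with age |

Ages are drawn per group from normals truncated to [18, 90] years with
the training-design means/SDs (46.5 ± 12 disease, 45.4 ± 16 healthy;
the testing design uses 42.5 ± 15 and 52 ± 15); the age trend is
centered on the pooled mean age so it is mean-neutral.  The global
scale factor is Normal(1, sd) truncated positive.

Features enter the SVM unstandardized on purpose: the weight-map and
weight-vs-z narratives tie raw coefficients to raw normalized
intensities, which per-feature standardization would destroy.

## The synthetic generator: what it does and does not emulate

Each scan is an ellipsoidal phantom (semi-axes 45% of the grid extent)
at constant baseline, with disease-group intensity multiplied by
(1 − effect) inside planted spheres — overlapping spheres combine by
max so effects never exceed 1 — plus the age trend, the global scale,
and i.i.d. Gaussian noise inside the brain mask (exact zero outside).
The default pattern is three spheres (radii 8–12 mm) loosely emulating
a multi-focal posterior/temporal/frontal hypometabolic distribution.
Default effect 0.3 for the headline run is a free parameter: the
motivating clinical analyses report peak T-values, not percent
reductions, so no patient-calibrated effect size exists.

Not emulated: gyral anatomy and gray/white contrast, scanner
point-spread and reconstruction physics, spatially correlated
physiological noise, inter-scanner offsets.  Passing tests therefore
demonstrate the statistical machinery (thresholds, cluster logic,
decoder, metrics) under a controlled noise model — not clinical
performance on real scans, where anatomy-locked variance and
registration error can only reduce accuracy.

## Numerical and design choices

- **Global normalization** is proportional scaling to a common in-mask
  mean.  Modeling global signal as an ANCOVA nuisance is the main
  alternative; proportional scaling was chosen as the dominant
  convention and because it makes decision scores comparable across
  subjects.  The choice is echoed in each run's provenance log.
- **Smoothing boundary**: reflection padding, which conserves the
  in-grid total and avoids edge attenuation inside the brain.  Order is
  smooth → normalize, logged.
- **Degenerate voxels**: zero residual variance yields t = 0, p = 1
  (excluded from masks); a cohort with constant age drops the age
  column with a warning rather than fitting a rank-deficient design.
- **z at extreme p**: p is clipped to [1e-300, 1 − 1e-16] before the
  quantile transform so z stays finite.
- **Cluster label order**: components are labeled by raster order of
  first voxel, then retained clusters relabeled by descending size —
  fully deterministic.
- **Mann-Whitney**: exact two-sided p by enumerating all C(n+m, n)
  group assignments of the pooled values for combined n ≤ 12 (ties
  handled by midrank counting, p = min(1, 2·min(P(U≤u), P(U≥u))));
  larger samples use the tie-corrected normal approximation with
  continuity correction.  The method used is always reported.
- **Reported precision**: metrics are kept at full precision in machine
  output; percent views at nearest-integer and one-decimal rounding are
  provided for human-readable reports.  Note 17/19 = 89.47% rounds to
  89.5 at one decimal while the classical report of that ratio prints
  89.4; the package reports the honest rounding.
- **Seeding**: a single config seed feeds named substreams (training
  cohort, testing cohort; within a cohort, ages then per-subject
  noise), so all artifacts are bit-reproducible.

## Calibration experiments

Two design choices in the validation experiments deserve explanation.

*Mask recovery is scored without smoothing.*  The recovery experiment
plants a 0.2-effect sphere (noise 10% of baseline, 50 subjects/group)
and scores the stage-1 mask by Jaccard overlap with the planted
support.  An 8 mm kernel spreads a high-SNR effect several millimetres
beyond its geometric support — the suprathreshold halo, not the
detector, would then dominate the overlap — so this experiment runs at
fwhm = 0 to measure the thresholding and cluster machinery itself.
The same reasoning applies to the null voxel-threshold calibration:
binomial bounds on the p < 0.005 pass fraction assume independent
voxels, which smoothing would violate.

*Null decoder calibration uses a fixed anatomical mask.*  With no
planted effect the stage-1 mask is (correctly) empty and the pipeline
aborts, so chance-level behaviour of the decoder is measured by scoring
signal-free cohorts through a fixed 10 mm sphere: same feature
extraction, training and scoring code, features carrying no group
signal.  Held-out accuracy over 20 repetitions stays within binomial
noise of 50%.

## Problem sizes

The default grid is a reduced-resolution template-like lattice of
48 × 56 × 48 voxels at 2 mm (full 91 × 109 × 91 MNI-like grids are
supported through the config).  The headline experiment uses the
published design sizes (train 100/44, test 19/20); the mask-recovery
experiment runs at 32 × 36 × 32 and the null calibrations at
26 × 30 × 26 and 24 × 28 × 24 with 20 repetitions.  These sizes were
chosen so a complete study, including calibrations, runs in seconds on
a single CPU while keeping every cluster comfortably above the k ≥ 200
extent threshold.

## Known limitations

- The phantom's constant-intensity brain makes the GLM's noise
  homoscedastic across voxels; real PET noise is intensity- and
  anatomy-dependent.
- Only the hypometabolic contrast is masked; a condition with mixed
  hyper/hypo patterns would need the second contrast direction.
- `C` is not cross-validated (by design, mirroring the fixed-default
  practice); on near-separable synthetic data the solution is
  insensitive to C over orders of magnitude.
- Exact Mann-Whitney is enumerative and restricted to tiny samples; the
  testing-set comparison (n = 39) always uses the approximation path.
- The two-scanner harmonization problem of real multi-site cohorts is
  out of scope; a scanner-offset stress test can be emulated by scaling
  one cohort's baseline.
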