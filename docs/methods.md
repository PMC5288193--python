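# Methods

## Overview

`prorad` implements a prostate radiogenomics analysis in five stages:

1. **Habitat delineation.** Contrast-vs-time curves from every prostate voxel
   of the DCE-MRI series are decomposed into a small number of nonnegative
   temporal patterns. The amplitude A of the tumor-like pattern (rapid
   wash-in, gradual washout) is thresholded at `mean(A) + k*stdev(A)` for
   k = 2, 1.5 and 1 into high/mid/low perfusion-risk bands. Independently,
   the ADC map is binned at 800, 1000 and 1200 um^2/s (lower ADC = more
   restricted diffusion = higher risk). A voxel's combined habitat
   probability is the intersection of the two band maps.
2. **Pharmacokinetics.** The extended Tofts model with the Parker population
   arterial input function is fitted to region-averaged DCE curves, yielding
   Ktrans, kep and ve per region.
3. **Feature extraction.** A canonical 49-feature vector per biopsy sample:
   25 patient-level features (gland/zone volumes; first-order T2w/ADC
   statistics and pharmacokinetics of the normal-appearing-tissue (NAT)
   reference regions; habitat probability-map volumes; extracapsular
   extension) and 24 ROI-level features (ROI volume; extended first-order
   statistics; ROI pharmacokinetics; ROI-habitat intersection volumes; zonal
   location). Grouped by provenance the counts are 4 volumes, 18 basic
   intensity statistics, 10 extended ROI statistics, 9 pharmacokinetic
   parameters, 6 probability-map volumes, 2 semantic features.
4. **Feature redundancy.** All C(49,2) = 1176 feature pairs are tested by
   Pearson correlation with Holm step-down adjustment.
5. **Radiogenomic correlation.** Genes are filtered for significant
   expression (removed when median < 0.25 AND IQR < 0.5 on the normalized
   scale), then each retained gene is Pearson-correlated with each feature;
   two-sided p-values use the exact t-transform with n-2 df and are
   Benjamini-Hochberg adjusted over the whole feature x gene family.
   Heatmaps and sample trees use hierarchical clustering on the correlation
   distance d = 1 - r with average linkage; per-feature lists of genes with
   raw p < 0.05 are exported for external enrichment tools.

## Model assumptions

* **Co-registration is given.** All volumes must share one voxel grid; the
  pipeline refuses resampling.
* **Enhancement is proportional to concentration.** No T1 mapping or
  signal-to-concentration conversion is performed; relative enhancement is
  treated as linearly proportional to tracer concentration. Fitted Ktrans
  values are therefore on a relative scale unless calibrated input is
  supplied. This proportionality cancels in ve and kep only partially
  (kep is scale-free; Ktrans and vp absorb the scale).
* **Extended Tofts.** C_t(t) = vp*Cp(t) + Ktrans * int_0^t Cp(s)
  exp(-kep (t-s)) ds. The plasma fraction vp is fitted but not exported as a
  feature; the exported triplet is (Ktrans, kep, ve) with ve = Ktrans/kep
  enforced by construction (the fit is parametrized over (ve, kep, vp) with
  ve in [0,1], kep in [1e-6, 20], vp in [0, 0.99]).
* **Parker AIF.** Sum of two Gaussians plus a sigmoid-gated exponential
  decay, with the published population constants stored in one overridable
  table; whole blood is converted to plasma by 1/(1 - Hct) with Hct = 0.42
  (configurable).

## Parameters that matter

| Parameter | Default | Units | Why |
|---|---|---|---|
| amplitude threshold multipliers k | 2, 1.5, 1 | - | high/mid/low perfusion risk cutoffs over prostate amplitude distribution |
| ADC cutoffs | 800, 1000, 1200 | um^2/s | established diffusion bands for tumor suspicion |
| DCE sampling | 13 frames at 30 s | - | 1 pre-contrast + 12 post-contrast frames; the frame spacing is configurable (the emulated acquisition reports only the number of post-contrast volumes) |
| quadrature step | 1 | s | trapezoidal convolution grid; error far below fit noise at 30 s sampling |
| hematocrit | 0.42 | - | blood-to-plasma AIF conversion |
| filter cutoffs | median 0.25, IQR 0.5 | normalized expression | removal rule is the literal AND; an OR mode is available behind a flag |
| alpha | 0.05 | - | both the raw and FDR significance cutoff |
| linkage | average | - | UPGMA on d = 1 - r; complete/single configurable |

## Numerical choices

* **Pattern decomposition** is nonnegative matrix factorization of the
  (prostate voxels x time) matrix, n_patterns = 3 by default. The solver is
  scikit-learn's coordinate descent from a deterministic NNDSVDa start (no
  random restarts), tol 1e-4, max 2000 iterations. Multiplicative updates
  were tried first and rejected: with a plain NNDSVD start their zero
  entries are absorbing, and their asymptotic convergence is slow enough
  that exactly factorizable test matrices stalled at ~5% reconstruction
  error. On noisy data the residual floor is the noise itself, so
  non-convergence is declared only for a max-iteration exit that left most
  of the signal unexplained (relative error > 0.5); tolerances tighter than
  1e-4 changed the fit by < 1e-4 while tripling iteration counts.
* **Tumor-pattern identification.** Patterns are normalized to unit maximum
  (amplitudes carry scale). A pattern is tumor-like when its peak falls in
  the first half of the post-contrast frames, its last-third trend is
  non-increasing, and it loses at least 10% of its peak by the final frame;
  among candidates the deepest washout wins, ties broken by earliest peak.
  The tail test is "slope <= 0" rather than strictly negative because a
  fully washed-out pattern has an exactly flat zero tail.
* **Thresholding conventions.** Amplitude bands use `>=` at each cutoff and
  the population (n) standard deviation; a constant amplitude map labels
  everything `none` with a warning. ADC bands are half-open on the left:
  high iff ADC <= 800, mid iff 800 < ADC <= 1000, low iff 1000 < ADC <=
  1200. The combined probability is the lower-risk (min) of the two parent
  labels and `none` if either parent is `none` - conservative, so a combined
  `high` requires both parents high. Bands are stored as disjoint strata;
  cumulative maps are derivable by `band >= level`.
* **First-order statistics.** Percentiles interpolate linearly between
  order statistics; StDev uses the n-1 denominator (configurable);
  skewness/kurtosis are population-moment Fisher g1 and excess kurtosis,
  defined as 0 for a constant region; Integral is the intensity sum times
  the voxel volume in cc.
* **Multiple testing.** Holm step-down for the 1176 redundancy pairs;
  Benjamini-Hochberg step-up over the full feature x gene family for the
  radiogenomic scan. Constant features or genes are excluded from the
  family with a warning rather than contributing undefined correlations.
* **Degenerate inputs.** All-zero enhancement, empty masks, negative ADC
  voxels, non-nested zone masks and missing region fits raise typed errors
  naming the offending input.

## The synthetic study

The generator emulates the targeted-biopsy study design so every stage can
be verified against ground truth without clinical data:

* **Geometry**: an ellipsoidal prostate on a 64x64x64 grid of 1x1x1.5 mm
  voxels, a central cylindrical urethra, a posterior peripheral zone (PZ),
  the transition zone (TZ) as the remainder, and spherical NAT references
  and biopsy ROIs placed by erosion-constrained random search so every ROI
  sits wholly inside its zone. PZ, TZ and urethra partition the gland
  exactly.
* **Signal**: T2w and ADC are region-mean Gaussian fields; tumor ROIs have
  low ADC (700 um^2/s) and rapid-washout kinetics (Ktrans 0.45 min^-1,
  kep 1.6 min^-1) against slow-enhancing PZ (0.05, 0.40) and intermediate
  TZ (0.12, 0.60) backgrounds. DCE voxel curves are exact forward-Tofts
  curves plus iid Gaussian noise (sd 0.02 concentration units by default;
  a zero-noise variant supports exact-recovery checks).
* **Cohort**: 17 biopsy samples over 6 patients; per-patient parameter
  jitter (10%) and variable ROI radii create between-sample feature
  variation.
* **Expression**: 200 genes x 17 samples on a SCAN-normalized-like scale.
  Three genes are planted as linear-plus-noise transforms of named radiomic
  features at |r| = 0.9; 15% of genes are low-expression (uniform on
  [0.02, 0.2]: median < 0.25 and IQR < 0.5, hence removable by the filter);
  the remainder is independent Gaussian noise.

What the generator does **not** emulate: MR physics (coil bias, distortion,
T1 saturation), partial-volume effects at region boundaries, spatially
correlated noise, intra-tumor heterogeneity, registration error, and any
realistic gene-gene covariance structure. Passing tests therefore
demonstrate the correctness of the computational pipeline under its stated
model, not the clinical sensitivity of habitat delineation.

## Verification studies and problem sizes

* Noiseless Tofts curves (13 frames at 30 s) refit to the truth within 1%
  relative over a 3x3x2 (Ktrans, kep, vp) grid; with 5% noise the median
  relative Ktrans error over 200 replicates stays below 10% (evaluated at
  the reference point Ktrans 0.2, kep 0.5, vp 0.02).
* On the zero-noise study the combined high-probability map recovers 100%
  of true tumor voxels; amplitude bands nest with k; ADC bins match a
  brute-force per-voxel loop on 10^4 random values.
* Null calibration: with independent Gaussian features and genes (n = 17,
  49 x 200 family, 500 replicates) the raw p < 0.05 rate is 5.0% and FDR
  discoveries average ~0.04 per replicate. Links planted at |r| = 0.9
  survive BH in ~93% of replicates under the generator's three-link design.
  (A single isolated planted link survives only ~83% of the time: its
  adjusted p-value then depends on being the family's smallest p, which a
  realized r near 0.83 no longer guarantees.)
* The unit-test suite runs the imaging stages on 48x48x40 and 32x32x24
  grids; the acceptance script runs the full default-scale (64^3) cohort
  twice to confirm byte-identical tabular outputs.

## Known limitations

* Ktrans/vp are scale-relative without a signal-to-concentration
  calibration; only ratios (kep, ve) are directly comparable across scanners.
* The pattern-decomposition rank and the tumor-pattern heuristic are
  heuristics; pathological acquisitions (no washout anywhere) fall back to
  the deepest-washout pattern with no guarantee it is tumor-related.
* The expression filter's AND reading cannot be validated against a real
  filtered-gene count without the original cohort; the OR variant is one
  flag away.
* Semantic features (ECE, ROI location) are pass-through inputs; nothing in
  the pipeline derives them from images.
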