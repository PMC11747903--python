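# Methods

This note documents the models, estimators and design choices in `octava`,
in the spirit of the methods documentation of statsmodels or msprime: what
is computed, under which assumptions, and where the defaults come from.

## The classification problem

Pulmonary-vein isolation succeeds when ablation lesions land on atrial
tissue just outside the PV ostia; lesions inside the vein risk stenosis.
Intensity OCT distinguishes the two walls through optics: the LA presents a
thin, highly scattering endocardium over dimmer myocardium — an abrupt
intensity falloff — while the PV wall (media/adventitia, collagen-rich)
decays more slowly, with deeper penetration and more heterogeneous texture,
and a lower attenuation coefficient. The pipeline turns that contrast into
a per-patch P(PV).

## Synthetic phantom generator

The generator produces the study conditions for every test; it emulates the
contrast above, not the physics of beam propagation (no wave optics, no
polarization — see Non-goals below).

Per A-line, linear intensity over depth-from-surface `z`:

* LA: `g·exp(-2·mu_LA·z)` for `z < t` (endocardium), `b·exp(-2·mu_LA·z)`
  below, with reflectivity gain `g` (default 4), myocardial baseline `b = 1`
  and endocardial thickness `t` drawn from a smooth spatial field over
  40–80 µm.
* PV: `(1 + m(z, x, y))·exp(-2·mu_PV·z)` with a low-spatial-frequency
  modulation field `m` (Gaussian-filtered noise, amplitude 0.35) supplying
  texture heterogeneity.
* Attenuation defaults `mu_LA = 0.6042 mm⁻¹`, `mu_PV = 0.5227 mm⁻¹` — the
  sample-average coefficients measured on human venoatrial junctions.
* Speckle: i.i.d. unit-mean exponential multiplicative noise per pixel
  (fully developed speckle) — the simplest model with the correct first
  moment. Spatial speckle correlation is NOT modeled.
* Geometry: depth 128 px at 3.67 µm/px (so a 64-px patch spans 235 µm); the
  x-axis splits into an LA band, a `transition_width`-wide band where the
  two profiles are convexly blended (weight linear in x, labeled
  TRANSITION), and a PV band; the band boundary wanders with y so the
  en-face boundary is irregular; the surface undulates smoothly with
  amplitude 0.02 mm so flattening is exercised.
* Display domain: `d = round(255·log(1+alpha·I)/log(1+alpha·I_ref))` with
  `alpha = 100` and a fixed reference intensity `I_ref = 10`, i.e. a fixed
  display gain across a study (so acquisition brightness differences carry
  into the 8-bit domain, as with a fixed-range export). The transform is
  monotone, preserving pixel ordering.

**Cohorts.** `generate_junction_set` adds specimen-level variability on top
of the per-volume randomness, because junction-grouped cross-validation is
only a meaningful generalization test if junctions differ systematically:
both attenuation coefficients jittered (sd 0.03 mm⁻¹, LA > PV ordering
preserved), endocardial gain and PV texture amplitude jittered log-normally
(σ = 0.20 / 0.25), a log-normal per-acquisition brightness factor
(σ = 0.25; this is what makes raw mean intensity a poor class cue, as in
multi-acquisition real data), and the LA fraction of the grid jittered
(σ = 0.05, clipped to [0.5, 0.85]) to mimic variable dissection extent. The
default cohort (26 junctions of 512 × 40 A-lines, `la_fraction = 0.70`,
transition 24) yields ≈3000 accepted patches at roughly 3:1 LA:PV,
LA-majority as in the real dataset, which exercises the class-weighting
machinery.

What passing tests on phantoms do NOT show: robustness to real-tissue
confounders (fibrosis, fat, trabeculation, catheter artifacts), to
correlated speckle, or to labeling noise. Phantom AUROCs are upper bounds
on what identical code achieves on real data.

## Surface detection and flattening

No standard algorithm exists for benchtop cardiac OCT surface finding; the
implementation is deliberately plain and fully configurable: a 5-px axial
median filter, Otsu threshold per B-scan, shallowest supra-threshold depth,
then a 7-A-line lateral median on the surface track. A-lines never crossing
the threshold are BACKGROUND. Flattening applies integer shifts only — 8-bit
values pass through untouched and each A-line keeps its multiset of tissue
pixels — and is idempotent. On a noiseless undulating phantom ≥99% of
detected surfaces are within 1 px of truth.

## Patch extraction

Non-overlapping 64 × 128 px tiles (depth × width), anchored at x = 0, one
tile row per B-scan, top 64 px only (deeper signal is roll-off dominated);
partial edge tiles discarded. Inclusion requires (1) ≥90% nonzero pixels,
(2) a single A-line label ∈ {LA, PV}, (3) no entirely-zero A-line.
Criterion 3 is read as "no A-line whose pixels are ALL zero": a literal
all-pixels-nonzero reading would subsume criterion 1. Alternative patch
sizes (32×32, 32×128, 64×32) are supported via `patch_shape`.

## Features

* **GLCM** (correlation, energy, contrast, homogeneity): 32 gray levels by
  uniform binning of 0–255, offsets (0,1) and (1,0) at distance 1,
  symmetric, normalized, features averaged over the two offsets — the
  standard Haralick setup. Energy is Σ P² (angular second moment). A
  constant patch has undefined correlation; it is set to 0 and logged.
* **Pixel statistics**: population moments (variance with denominator N,
  kurtosis as excess), entropy in bits over the 256-bin histogram.
  Consistency matters more than convention; both choices are fixed and
  documented here.
* **Attenuation**: the depth-resolved estimator
  `mu_i = I_i / (2·dz·Σ_{j>i} I_j)` on linear-domain intensity, scale
  invariant, uncorrected for finite imaging depth. The last `tail_exclude`
  = 8 rows are dropped (denominator unreliable). On a 64-px window the
  truncated tail biases the absolute scale upward for both classes; the
  LA > PV ordering and the discriminative value are unaffected, and on deep
  noiseless phantoms the estimator recovers mu within 3%. Patch scalars are
  the mean and population SD over valid pixels; patches with <10 valid
  pixels are dropped with a warning.

## Feature engineering

Welch-corrected t-tests run on per-junction average feature values (one LA
and one PV average per junction — the specimen, not the patch, is the unit
of inference); single-feature AUROC (PV positive, oriented as
max(a, 1−a) for gating) and all-pairs Pearson correlations run on
patch-level values. Random-forest impurity importances are averaged across
the CV folds' training sets. Selection: drop oriented AUROC < 0.6; then
prune each |ρ| ≥ 0.7 pair greedily in descending importance (keep the more
important member — ties and chains resolve naturally in that order); keep
the top 4 survivors by importance. The full audit trail (per-feature
rejection reason) is returned.

## Classifiers

LR and RF follow scikit-learn defaults where not specified: LR with the L2
penalty at coefficient 1.0 on standardized features, RF with 100 Gini trees
on unscaled features; both are refit on train + validation junctions
combined. The Standardizer and CNN class weights are computed from training
rows only (leakage-guarded by tests).

The CNNs run on an in-package NumPy engine (`octava.nn`) with explicit
reverse-mode gradients: im2col + GEMM convolution in NHWC layout, exact
first-match max-pool subgradients, inverted dropout, Adam. Architectural
anchors: 4 conv layers, 3×3 kernels, channels 32→64→128→256 chosen so a
1×64×128 input flattens to exactly 8192 = 256·4·8; dropout p = 0.15 after
conv blocks 2 and 4; V1 head 8192→12 (+4 features → 16→1), V2 head
8196→1. The channel progression, kernel size and dropout placement are
package choices around the fixed layer count and embedding/head widths.
Training recipe: Adam (chosen as the fixed optimizer), lr 1e-4, batch 256,
class weights ∝ inverse frequency renormalized to mean 1, augmentation by
50% left–right (width-axis) flips — depth is physically asymmetric, so
depth flips are excluded — pixels mapped uint8 → [0,1], engineered features
standardized with the training Standardizer. Model selection: best
validation-AUROC checkpoint, early stopping (patience 10 by default, and
immediately once validation AUROC ≥ 0.999); without a validation set the
run falls back to fixed-epoch training with a warning.

## Evaluation

`make_cv_plan` permutes junction IDs with a seed and cuts test blocks of
size ⌈n/7⌉ (the last block absorbs the remainder; every block non-empty).
For n = 26 this reproduces test sizes (4,4,4,4,4,4,2). Validation
junctions are drawn, seeded, from the non-test remainder with the same
nominal size — giving 18/4/4 for six folds and 20/4/2 for the last — rather
than rotating the next test block cyclically, which would make the final
fold's validation set 2 instead of 4. Metrics are computed per fold and
summarized as mean ± SD across folds (no pooled micro-averaging). MCC uses
the standard 2×2 formula with the 0-by-convention fallback when a marginal
is empty (flagged in the output); normMCC = (MCC+1)/2 exactly. ROC/AUROC
use a threshold sweep with trapezoidal integration, which equals the
rank-based (Mann–Whitney) statistic with ties at ½. Grad-CAM weights the
last conv layer's activations by globally averaged score gradients
(PV score = the logit, LA score = its negation), rectifies, bilinearly
upsamples and max-normalizes; an all-zero gradient yields an all-zero map.

## Problem sizes and numerical choices

The default synthetic study runs 26 junctions (≈3000 patches). LR and RF
are evaluated on all seven folds. The CNNs' CPU cost dominates, so the
patch CNN is evaluated on one fold with both classes in its test set, with
training capped at 1024 patches (class-stratification left to chance) and
≤20 epochs; the phantom's designed contrast saturates validation AUROC
well within that budget. The null (label-shuffle) check uses a 10-junction
cohort, 256 training patches and 2 epochs per CNN — an undertrained null
model is a valid leakage guard, since only leakage could move grouped
held-out AUROC off chance.

Float32 throughout the network; probabilities within one inference batch
can differ at ~1e-7 across row positions (GEMM blocking), which is the
tolerance tests use for "identical" duplicated inputs. Fold metrics with
empty denominators (e.g. a test fold that drew junctions without clean PV
patches — possible at wide LA fractions, as in real dissections) are
reported as NaN with an `undefined` flag and skipped in summaries.

## Known limitations

* The attenuation scalar on 64-px patches is biased upward by tail
  truncation; it is a texture-like discriminative feature here, not a
  calibrated optical-property measurement.
* The phantom lacks correlated speckle, multi-layer PV wall structure, and
  pathology-driven remodeling; phantom performance overstates real-data
  performance.
* Grad-CAM on the fusion variants attributes only the image pathway; the
  engineered-feature contribution is not visualized.
* The engine is CPU-only and sized for desk-scale experiments, not for
  training on tens of thousands of patches.
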