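# Methods

This note documents the models, conventions and design choices behind
`radsurv`, and what its synthetic validation does and does not establish.

## Synthetic cohorts

The generator (`radsurv.synthetic`) emits, per subject:

* **MR-like volumes.** Inside an ellipsoid ROI, intensity is
  `base + contrast · G` where `G` is a Gaussian random field (white noise
  smoothed with a Gaussian kernel, σ = 1.5 voxels by default, then
  standardized within the ROI). `contrast` is the in-ROI intensity standard
  deviation — the texture-heterogeneity parameter. Outside the ROI the
  volume is a constant background. PD-like and CET1-like volumes get
  independent fields and contrasts.
* **PK truth fields.** Per-subject mean `Ktrans`, `ve`, `vp` are modulated
  voxel-wise by a mean-preserving log-normal factor (spatial CV 0.3 by
  default); `ve` and `vp` are clipped to physiological ranges and rescaled
  so `ve + vp ≤ 1` everywhere.
* **DCE series.** Tissue concentration follows the extended Tofts forward
  model under a fixed analytic population AIF (linear bolus ramp over
  0.25 min to 5 mM, then a 0.6/0.4 bi-exponential decay with rates 3.0 and
  0.2 min⁻¹), evaluated by an exact piecewise-linear convolution, plus
  additive Gaussian noise (0.02 mM by default; 0 gives a noiseless series).
  A shared analytic AIF was chosen over patient-specific arterial sampling
  because it is reproducible and sufficient for recovery testing.
* **Survival.** Each covariate channel has a latent draw z ~ U(−1, 1); the
  physical parameter is the channel's range midpoint plus z times its
  half-width, so z is exactly the standardized ground-truth covariate.
  PFS is exponential proportional hazards, `T = −log U / (h0 · exp(βᵀz))`
  with `h0 = 0.02` events/month and β = 1 on the PD contrast, CET1 contrast
  and mean-Ktrans channels by default. The hazard deliberately depends on
  the *latent truth*, not on extracted features, so feature→risk recovery is
  a genuine end-to-end test. Censoring is an independent exponential time
  whose rate is calibrated (by root finding on the exact censoring
  probability `μ/(μ+λᵢ)`) so the expected censored fraction matches the
  configured rate (0.3 by default). A Weibull baseline is a possible config
  extension; the exponential inverse transform is the simplest generator
  with closed-form checks.

Identical configuration (including the seed) reproduces the cohort bit for
bit; per-subject RNG streams are derived from `(seed, subject_index)`.

**What the phantoms do not emulate:** MR physics (coil bias fields, motion,
partial-volume effects), anatomy, signal-to-concentration conversion,
scanner- or protocol-dependent intensity distributions, and non-proportional
or non-exponential hazards. Passing tests therefore demonstrate the
*correctness of the computational pipeline* — exact feature definitions,
consistent estimators, honest selection — not the clinical performance of
any model on real tumors.

## Pharmacokinetic mapping

The extended Tofts model is fitted by its exact linearization: regressing
`Ct(tᵢ)` on `∫₀ᵗⁱ Cp`, `∫₀ᵗⁱ Ct` and `Cp(tᵢ)` (cumulative trapezoid
integrals) and recovering `kep = −b`, `vp = c`, `Ktrans = a − kep·vp`,
`ve = Ktrans/kep`. The linear route is deterministic and needs no starting
values; its price is integration bias at coarse temporal sampling, which the
tests bound (error decreases with temporal resolution; < 1% relative at 60
points over 5 min).

Conventions: voxels with an identically zero concentration curve are valid
null tissue (all parameters 0, `fit_ok` true). Voxels with `kep ≤ 0` or
volume fractions outside [0, 1] are *flagged*, not silently clipped;
`clip=True` gives the clipped variant. The `ve = Ktrans/kep` identity is
enforced to 1e−6 relative on every fitted voxel at export. A singular design
(e.g. an all-zero AIF) flags all voxels and logs a warning.
Signal-to-concentration conversion is out of scope: the fitter consumes
concentration series directly.

## Radiomic features

* **Discretization:** fixed bin width (default 5 intensity units) anchored
  at the in-ROI minimum, `level = floor((x − min)/w) + 1`; levels are
  invariant to global intensity shifts. The same width applies to original
  and filtered images; it is a config field so it can be overridden per
  image type (the pipeline uses per-parameter widths for PK maps, whose
  physical scales are far below MR intensities: 0.02 for Ktrans, 0.05 for
  kep, 0.02 for ve, 0.005 for vp — roughly 25–50 levels over the plausible
  range of each).
* **Neighborhoods:** 26-connectivity in 3-D for GLSZM zones and GLDM/NGTDM
  neighborhoods, degenerating to 8-connectivity on single slices; GLCM uses
  the 13 unique direction classes at distance 1, with per-direction features
  averaged (not a merged matrix).
* **First order:** population variance (divide by N); RMAD is the mean
  absolute deviation of the values between the 10th and 90th percentile
  inclusive; kurtosis is non-excess; entropy/uniformity use the fixed-bin
  histogram.
* **Degenerate conventions:** a single gray level gives MCC = 1,
  NGTDM Complexity = 0; a single-voxel ROI has GLDM dependence 1.
* **Filters:** one-level stationary wavelet (coiflet-1), normalized so the
  8-sub-band bank conserves energy; sub-band letters map to axes in array
  order (L = approximation, H = detail). LBP is slice-wise 2-D (radius 1,
  8 samples, uniform patterns) on edge-padded slices so border pixels see
  in-image neighbors. Square root is `√|x|`.
* **Shape:** voxel-count volume; surface area from a marching-cubes mesh of
  the lightly Gaussian-smoothed mask (σ = 1 voxel), which removes the
  staircase bias of a binary mesh — a digitized radius-10 ball comes out
  within 5% of sphericity 1. Tiny masks whose smoothed maximum falls below
  the 0.5 level set fall back to the binary mesh.
* The catalog is a curated standard set (19 first-order, 6 GLCM, 15 GLSZM,
  13 GLDM, 5 NGTDM per image) rather than a maximal one; full parity with
  any particular platform's 1600+ feature list is a non-goal.

## Feature maps

Patches are 2-D per slice (window × window, default 21, odd), clipped at
image borders and restricted to patch∩ROI; the named feature is computed on
that restriction — with discretization re-anchored at the *patch* minimum by
default (`global_origin=True` anchors at the volume-wide in-ROI minimum
instead) — and assigned to the center pixel. Visited centers lie on the
grid `window//2 + k·step`, so `step = window` tiles the slice and reproduces
direct per-tile extraction exactly. Pixels whose patch covers less than
`min_roi_fraction` of the window (default 0.25) or restricts to fewer than
two voxels are left undefined. A window larger than the shortest in-plane
ROI bounding-box edge triggers a warning, not an error. 3-D patches and
automatic window selection are out of scope.

## Model construction

* **Cleaning** drops features with missing values, zero variance or exact
  duplicates (first occurrence kept); it is idempotent.
* **Redundancy filter:** greedy scan in column order; a later feature is
  dropped when |Pearson r| with any kept feature exceeds 0.8. Column-order
  tie-breaking makes runs reproducible.
* **LASSO-Cox:** features are standardized to training mean/SD before
  penalization (penalties need a scale convention; the standardization is
  stored on the model). The λ grid runs from the all-zero λ_max down two
  decades (50 values); λ is chosen at minimum cross-validated
  partial-likelihood deviance using the Verweij–van Houwelingen
  cross-validated log partial likelihood over event-stratified folds
  (default 10, reduced to the event count when events are scarce).
* **Backward elimination** refits the multivariate Cox model and removes the
  single largest-p feature while any p ≥ 0.05, stopping at one feature.
* **VIF:** `1/(1 − R²)` from regressing each feature on the others with
  intercept; > 5 is flagged, exact collinearity reports infinity.
* **Cox fit:** Breslow tie handling (lifelines). Monotone likelihood or
  separation falls back to a ridge-penalized refit (escalating penalty),
  flagged in the model provenance. Constant covariates are dropped before
  fitting — they carry no information and break Newton steps; this matters
  when an upstream model is empty and its prediction is constant. A model
  with no features is valid and scores every subject 0. The training-median
  linear predictor is stored as the risk cutoff.
* **Combined model:** redundancy-filter the DCE features, drop those with
  |r| > 0.8 against the MR model's linear predictor (the same 0.8 as
  feature–feature redundancy; "highly correlated" needs one number), pool
  the survivors with the MR prediction, re-run LASSO + backward elimination,
  refit. If every DCE feature dies, the MR model is returned unchanged and
  flagged. If the MR model is empty, its constant prediction is omitted
  from the pool.
* **Splitting:** event-stratified 7:3 with exact sizes; a split leaving a
  part without events is reshuffled with a warning.

## Evaluation

Harrell's C counts pairs whose earlier time is an event; score ties count
1/2. Confidence intervals are percentile bootstrap over subjects (1000
resamples by default); resamples without comparable pairs are redrawn.
Risk groups use the training-median cutoff, ties at the cutoff going to the
low-risk group. The NRI is the categorical two-group variant at a fixed
horizon: events are progressions by the horizon, non-events are subjects
followed past it, and subjects censored before the horizon are excluded
(their status is unknown). NRI for censored data is method-dependent and
easy to over-read, so the report always includes the raw reclassification
counts; treat the index as descriptive.

## Orchestration and problem sizes

`run_study` executes the full dependency graph with stage caching keyed by a
hash of the configuration; per-stage seeds derive from the master seed by
fixed offsets, and a rerun with the same configuration reproduces the report
byte for byte. The default study — 60 subjects, 32³ voxel volumes, 30 DCE
time points, ~1250 MR features and ~2500 DCE features per subject — runs in
a few minutes on one CPU; the validation simulations use 200 subjects with
50 direct covariates, where feature extraction is not the question. At 42
training subjects the cross-validated LASSO frequently and correctly selects
*nothing* for some seeds (the honest answer when evidence is thin); the
empty model scores everyone identically and evaluates at C = 0.5.

## Known limitations

* The linear Tofts estimator is biased at coarse temporal sampling and high
  noise; a nonlinear refinement is not implemented.
* Texture features are exact per their definitions but the catalog is
  curated, not exhaustive; GLRLM is absent. Where the same abbreviation
  exists in several families (e.g. GLNN), the family is always part of the
  feature name — here GLNN is reported from GLSZM.
* The NRI variant requires a horizon within follow-up and both events and
  non-events at that horizon; it errors otherwise.
* Synthetic validation bounds implementation error, not clinical validity;
  results on real cohorts depend on acquisition, segmentation and
  signal-to-concentration conversion, all outside this package.
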