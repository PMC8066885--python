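# Methods

This note documents the models implemented in `natriq`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical and design decisions a maintainer should know about.

## Signal model and calibration

Sodium MRI with an ultrashort-echo, spin-density-weighted acquisition
measures a signal proportional to total sodium concentration (TSC), the
volume-weighted average of intra- and extracellular sodium. The package
converts signal to mM with a two-point affine calibration through two
internal references: the vitreous humour of the eyes (assumed 140 mM) and
the background noise (0 mM). The calibration line passes through the two
region **means** (the median is available by option); both eyes are pooled
into one reference mask. No relaxation-time (T1/T2) correction is applied —
tissue-specific sodium relaxation during injury is not well characterized,
so the maps carry the usual spin-density-weighting caveat.

When the acquisition is blurred by a point spread function (PSF), voxels at
the rim of the vitreous are averaged with the dark exterior and read low.
The pipeline therefore takes the vitreous reference mean over the mask
eroded `round(1.5 × FWHM)` times (stopping early rather than emptying the
mask on small eyes). On the default 64³ phantom this keeps the reference
bias at the 0.1% level; without erosion it reaches ~15% and propagates
directly into every concentration estimate.

## Global GM/WM estimation by partial-volume regression

Per voxel the TSC map is modelled as a three-compartment mixture

    TSC = C_GM f_GM + C_WM f_WM + C_CSF f_CSF ,

with C_CSF fixed at 140 mM and the tissue fractions taken from probability
maps convolved with the PSF, so the regressors live at the same resolution
as the blurred measurement. The known CSF term is moved to the observation
side and the over-determined two-column system is solved by ordinary least
squares over all brain voxels ("brain" = tissue-fraction sum ≥ 0.5 by
default, configurable). Design choices:

- **PSF form.** The true PSF of the non-Cartesian sodium trajectory is not
  published; an isotropic Gaussian at the stated FWHM of 2.65 voxels is the
  FWHM-faithful stand-in. Kernels are explicit objects (truncated at
  3.5 σ, renormalized, separable), so a measured PSF can be substituted.
- **Boundary handling.** Zero-padding, consistent with zero-signal air.
- **No non-negativity constraint.** Estimates stay linear-least-squares so
  the residual diagnostics remain valid; negative estimates are a
  mis-specification signal, not something to hide.
- **Rank checking.** The design's singular values are checked at a relative
  tolerance of 1e-10; a collinear f_GM/f_WM design raises a named error
  rather than returning an arbitrary pseudo-inverse solution.

Diagnostics mirror standard practice: an absolute-residual map, the RMS
residual, and a normal-probability (Q–Q) plot of the signed residuals with
the Pearson correlation of its quantile pairs as a scalar normality index.

Omitting the fraction convolution on blurred data biases the GM estimate
upward (CSF spill-in), which the test suite asserts as a directional
regression test for the correction's purpose.

## ROI voxel averaging and exclusion rules

ROI metric values are voxel means after a fixed filter chain restricting
the ROI to normal-appearing tissue: (1) subtraction of manually outlined
findings (lesions), (2) one-voxel erosion for CSF-adjacent ROIs (cortical
GM, thalamus-like deep GM), (3) exclusion of voxels with CSF fraction
strictly greater than 0.3, (4) a single one-sided outlier pass removing
values above mean + 2 × sample SD. The order is fixed: geometric filters
first, outliers last, because the outlier threshold depends on the
surviving distribution; the pass is applied once, not iterated. Erosion
uses 6-connectivity (faces only), the most conservative reading of "one
voxel". Sample (n−1) SDs are used throughout. Masks at a different
resolution than the metric map are resampled nearest-neighbour before
filtering; registration estimation is out of scope.

Each summary carries a ledger of the voxel count after every stage, and an
ROI emptied by a filter raises an error naming the stage.

Note the direction of the partial-volume bias for sodium: CSF at 140 mM is
~4× hotter than parenchyma, so CSF spill-in biases ROI means **high**; the
CSF filter and erosion reduce, but do not eliminate, that contamination.
This is the central reason the regression estimate is preferred for global
questions.

## Cohort statistics

- **Cohen's d** uses the pooled SD with n_p + n_c − 2 degrees of freedom and
  the patient-minus-control sign convention.
- **CV** is 100·SD/mean, with a helper that reports integer percents.
- **Exact Mann–Whitney.** The null distribution of the rank-sum is built by
  a shift/convolution dynamic program over the pooled midranks (doubled to
  stay integral under ties), so tied data keep permutation exactness. The
  two-sided p is min(1, 2·min(P(U ≤ u), P(U ≥ u))). Subset counts are exact
  integers in float64 up to a combined n of 50 (C(50,25) < 2⁵³), which is
  the enforced cap; the study-scale n = 43 is comfortably inside it.
- **Spearman correlations** are Pearson correlations of midranks with
  t-approximation p values (df = n − 2); the partial variant applies the
  first-order partial-correlation formula to the pairwise rank correlations
  with df = n − 3.
- **ANCOVA** is the main-effects linear model `value ~ group + covariate`
  (no interaction, no centering — the group coefficient is unaffected).
- **Recovery dichotomy**: GOSE 8 = recovered, 1–7 = non-recovered.
- No multiple-comparison correction is applied; tests are two-sided.
- Age-matching exclusions are an explicit id list in the configuration,
  never inferred from the data.

## Synthetic phantoms and cohorts

The phantom is a concentric-shell head: WM core, GM shell, CSF rim, a
central CSF ventricle, an optional deep-GM nucleus inside the WM, plus two
vitreous spheres placed antero-laterally outside the head and a zero-signal
background. Partial-volume fractions come from evaluating the geometry on a
3× super-sampled grid and box-averaging the region indicators, so fractions
sum to exactly 1 inside the head with closed-form ground truth and no
segmentation step. Default concentrations are the healthy-control values
(GM 37.9, WM 31.6, CSF = vitreous 140 mM); the forward model is Gaussian
PSF blur (FWHM 2.65 voxels) → linear gain → additive Gaussian noise
(default SD 1.8 mM-equivalent, i.e. SNR ≈ 20 against GM). Additive
Gaussian noise keeps the regression unbiased for testing; a magnitude
(Rician) channel is deliberately not the default. The eyes are pushed far
enough from the head that the truncated PSF cannot mix vitreous signal into
brain voxels — which is what makes the noiseless matched-kernel fit exact
to machine precision, a property the tests rely on. The vitreous reference
mask contains only pure (fraction-1) eye voxels so that blur-free
calibration is exact; grids too small to hold all regions raise a sizing
error (the geometry is comfortable from ~40³; the default is 64³).

Simulated cohorts default to 24 patients (GM ~ N(34.4, 2.1), WM ~
N(30.0, 3.2)) and 19 controls (GM ~ N(37.9, 1.4), WM ~ N(31.6, 1.6)). The
cognitive composite z-score is coupled to patient GM TSC through a Gaussian
copula at a target Spearman correlation (default 0.55, the strongest
reported TSC–cognition association); the six BTACT subtests are generated
around the composite with per-subject mean-zero deviations so the composite
equals the subtest mean identically. GOSE is assigned from the composite
ranking (top ~30% recovered), guaranteeing both recovery outcomes exist;
RPQ totals and subscales are plausible-valued covariates, negatively
coupled to cognition.

What the synthetics do **not** emulate: real anatomy (cortical folding,
skull, heterogeneous eyes), the true non-Gaussian PSF of the spiral
readout, B0/B1 inhomogeneity, relaxation weighting, registration and
segmentation error, and any physiologic within-tissue concentration
heterogeneity. Passing tests therefore demonstrate correctness of the
estimators under the stated forward model — not robustness to everything a
scanner does.

## Precision comparison between regression and ROI averaging

To compare estimator precision the tests simulate 19 control acquisitions
in which tissue concentrations are held fixed while each "subject" carries
small seeded anatomical jitter (±3% on head radius and shell thicknesses)
plus acquisition noise. ROI means then vary across subjects through
subject-specific CSF partial volume at the pial boundary, while the
regression corrects for it via the convolved fractions — reproducing the
mechanism by which regression achieves roughly half the CV of ROI averaging
on real control data. With concentrations fixed, the observed ordering
(regression CV ≈ 0.4%, ROI CV ≈ 1%) isolates exactly that mechanism.

## Problem sizes and tolerances

Test and acceptance computations use 64³ grids (40–48³ for unit tests),
50 noise replicates for bias checks, 19 subjects for the precision
ordering, and 500 seeds for the cohort effect-size calibration; the full
simulated pipeline at 64³ completes in seconds on one CPU. Fraction-closure
and calibration round-trips are asserted at 1e-9, least-squares against the
normal-equations oracle at 1e-10, matched-kernel recovery at 1e-6 mM, and
Monte-Carlo quantities at 2–10% depending on their sampling error.

## Known limitations

- The Gaussian PSF is a stand-in; quantitative bias from a mismatched
  kernel shape is not modelled (the kernel is pluggable for that reason).
- The exact Mann–Whitney is capped at combined n = 50; larger samples need
  the normal approximation (not implemented — out of scope for this study
  size).
- ANCOVA parameterization is the simplest main-effects model; interaction
  or centering variants must be fit directly with statsmodels if needed.
- Negative residual structure near ventricles reported for real data (a
  possible quadrupolar signal-loss effect) has no correction here, since
  none is established.
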