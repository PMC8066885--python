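# natriq

Quantitative sodium (²³Na) MRI analysis for the brain: total sodium
concentration (TSC) mapping with internal-reference calibration, global
grey/white-matter sodium estimation by partial-volume linear regression, ROI
voxel averaging with CSF and outlier exclusion rules, and the non-parametric
cohort statistics used in small clinical imaging studies (e.g. mild
traumatic brain injury vs. controls).

It is aimed at imaging scientists who have sodium signal volumes plus tissue
segmentations (NIfTI) and subject tables (CSV), and who want a tested,
reproducible implementation of this processing chain. Because clinical
sodium datasets are rarely shareable, the package ships a first-class
synthetic module — seeded digital head phantoms and simulated cohorts — so
the entire pipeline can be exercised, validated and benchmarked without any
patient data.

## The model

TSC measured by ²³Na MRI is the volume-weighted average of intra- and
extracellular sodium. Per voxel, the signal is modelled as a
three-compartment mixture

```
TSC = C_GM · f_GM + C_WM · f_WM + C_CSF · f_CSF
```

where `f_GM, f_WM, f_CSF` are tissue fractions from probability maps
**convolved with the imaging point spread function** (isotropic Gaussian,
FWHM 2.65 voxels by default), `C_CSF = 140 mM` is known, and the global
unknowns `(C_GM, C_WM)` are estimated by ordinary least squares over all
brain voxels. Convolving the fractions makes the regressors commensurate
with the blurred measurement and corrects the spill-over from CSF, whose
sodium concentration is ~10-fold higher than parenchyma — so the fit is
largely immune to partial-volume effects and highly sensitive to diffuse,
global concentration changes.

Upstream, signal volumes are converted to mM by a two-point calibration
through the vitreous humour of the eyes (140 mM) and the background noise
(0 mM). Downstream, the package provides ROI voxel averaging after lesion
subtraction, one-voxel erosion of CSF-adjacent ROIs, a strict CSF-fraction
filter (> 0.3 excluded) and a single one-sided outlier pass
(> mean + 2 SD); and cohort statistics: Cohen's d with the pooled SD,
coefficients of variation, an exact (permutation-null, tie-aware)
Mann–Whitney U test, ANCOVA, direct and partial Spearman correlations, and
the GOSE recovery dichotomy.

## Worked example

Simulate a patient-like acquisition and recover the global concentrations:

```python
import natriq as nq
from natriq.pipeline import eroded_reference_mask

# ground truth: patient-level concentrations
phantom = nq.build_phantom(nq.PhantomSpec(seed=42, c_gm=34.4, c_wm=30.0))
signal = nq.simulate_acquisition(phantom, seed=43)   # PSF 2.65, noise 1.8

vitreous = eroded_reference_mask(phantom.vitreous_mask.data, 4)
model = nq.fit_two_point(signal, phantom.background_mask.data, vitreous, 140.0)
tsc = nq.apply_calibration(signal, model)

kernel = nq.gaussian_psf_kernel(2.65)
conv = nq.convolve_fractions(phantom.fractions, kernel)
mask = nq.select_brain_voxels(conv, 0.5)
fit = nq.solve_global_tsc(tsc, conv, c_csf=140.0, brain_mask=mask)
print(f"C_GM = {fit.c_gm:.2f} mM   C_WM = {fit.c_wm:.2f} mM")
print(f"voxels used = {fit.n_voxels_used}   rms residual = {fit.rms_residual:.2f} mM")

table = nq.simulate_cohort(nq.CohortSpec(seed=7))     # 24 patients / 19 controls
comp = nq.compare_groups(table, "gm_tsc")
print(f"GM TSC: patients {comp.mean_p:.1f} ± {comp.sd_p:.1f} mM, "
      f"controls {comp.mean_c:.1f} ± {comp.sd_c:.1f} mM")
print(f"Cohen's d = {comp.cohens_d:.2f}   exact MW p = {comp.mw_p_value:.2g}")
```

prints

```
C_GM = 34.76 mM   C_WM = 30.13 mM
voxels used = 29344   rms residual = 1.81 mM
GM TSC: patients 33.6 ± 1.7 mM, controls 37.6 ± 1.2 mM
Cohen's d = -2.69   exact MW p = 1.1e-10
```

The fitted concentrations sit within ~1% of the simulated truth (34.4 /
30.0 mM) despite the blur and noise — the point of the PSF-aware
regression — and the simulated cohort shows the expected large negative
effect size (patients below controls) with a strongly significant exact
rank test.

The same chain is available from the shell:

```
natriq simulate --seed 42 --out work/
natriq run --seed 42 --out work/full     # full pipeline + JSON run report
natriq calibrate --signal s.nii.gz --noise-mask n.nii.gz \
    --vitreous-mask v.nii.gz --c-ref 140 --out tsc.nii.gz
```

## Layout

- `src/natriq/grids.py` — voxel-grid containers, NIfTI I/O
- `src/natriq/phantom.py` — head phantoms, forward model, cohort simulation
- `src/natriq/calibration.py` — two-point internal-reference calibration
- `src/natriq/regression.py` — PSF kernel, fraction convolution, global fit
- `src/natriq/roi.py` — ROI filter chain and summaries
- `src/natriq/cohort.py` — effect sizes, exact rank tests, correlations
- `src/natriq/pipeline.py`, `src/natriq/cli.py` — configured pipeline + CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
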