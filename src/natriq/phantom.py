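"""Digital head phantoms, simulated sodium acquisitions, and simulated cohorts.

The study whose analysis chain this package implements released no imaging
data, so every downstream stage is exercised against synthetic inputs with
the statistical structure the analysis assumes:

* a head-like concentric-shell geometry (WM core / GM shell / CSF rim, a
  central CSF ventricle, and an optional deep-GM "thalamus" nucleus) whose
  GM/WM/CSF fractions sum to exactly 1 inside the head and 0 in background;
* two spherical vitreous-humour "eyes" at 140 mM outside the brain, used as
  the non-zero internal calibration reference, plus a zero-signal background;
* ground-truth compartment concentrations defaulting to the healthy-control
  values (GM 37.9 mM, WM 31.6 mM, CSF 140 mM);
* a forward model: PSF blurring (Gaussian, FWHM 2.65 voxels) of the true TSC
  volume, a linear gain, and additive Gaussian noise;
* simulated patient/control cohorts (default 24 / 19) with group-wise GM/WM
  TSC distributions and a Gaussian-copula rank association between GM TSC
  and a cognitive composite z-score.

Partial-volume voxels are produced by evaluating the geometry on a 3x
super-sampled grid and box-averaging the region indicators, which gives
reproducible fractions with closed-form ground truth and no segmentation
step.  All randomness is drawn from one seeded generator per call; seeds are
required, not defaulted.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, InputError, SizingError
from .grids import TissueFractionMaps, VoxelGrid
from .regression import gaussian_psf_kernel, convolve_volume

__all__ = [
    "PhantomSpec",
    "Phantom",
    "CohortSpec",
    "build_phantom",
    "two_compartment_tsc",
    "simulate_acquisition",
    "simulate_cohort",
    "save_phantom",
    "BTACT_SUBTESTS",
]

# ROI label codes assigned by build_phantom
ROI_CORTICAL_GM = 1
ROI_GLOBAL_WM = 2
ROI_DEEP_GM = 3

SUPERSAMPLE = 3  # linear super-sampling factor for partial-volume fractions


@dataclass(frozen=True, kw_only=True)
class PhantomSpec:
    """Parameters of a digital head phantom and its default acquisition.

    Concentrations are in mM; geometric quantities in voxels unless a
    fraction of the smallest grid dimension is indicated.
    """

    seed: int
    grid_shape: tuple = (64, 64, 64)
    voxel_size: tuple = (1.5, 1.5, 1.5)
    c_gm: float = 37.9
    c_wm: float = 31.6
    c_csf: float = 140.0
    c_vitreous: float = 140.0
    psf_fwhm: float = 2.65
    noise_sd: float = 1.8
    lesion_fraction: float = 0.0
    # geometry knobs (fractions of min(grid_shape) unless stated)
    head_radius_frac: float = 0.30
    csf_rim_voxels: float = 2.0
    gm_shell_voxels: float = 4.0
    ventricle_radius_frac: float = 0.05
    eye_radius_frac: float = 0.09
    deep_gm_nucleus: bool = True
    geometry_jitter: float = 0.0  # relative SD of seeded anatomical jitter

    def __post_init__(self):
        shape = tuple(int(s) for s in self.grid_shape)
        object.__setattr__(self, "grid_shape", shape)
        if len(shape) != 3 or any(s < 16 for s in shape):
            raise DomainError(f"grid_shape components must be >= 16, got {shape}")
        for name in ("c_gm", "c_wm", "c_csf", "c_vitreous"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.psf_fwhm < 0:
            raise DomainError("psf_fwhm must be >= 0")
        if not 0 <= self.lesion_fraction < 1:
            raise DomainError("lesion_fraction must be in [0, 1)")
        if self.geometry_jitter < 0:
            raise DomainError("geometry_jitter must be >= 0")


@dataclass
class Phantom:
    """A built phantom: fractions, ground-truth TSC, and reference masks."""

    spec: PhantomSpec
    fractions: TissueFractionMaps
    truth_tsc: VoxelGrid
    vitreous_mask: VoxelGrid
    background_mask: VoxelGrid
    lesion_mask: VoxelGrid
    roi_labels: VoxelGrid
    head_mask: VoxelGrid
    geometry: dict = field(default_factory=dict, repr=False)


def _jittered(rng, value: float, rel_sd: float) -> float:
    if rel_sd == 0:
        return value
    return value * float(1.0 + rel_sd * rng.standard_normal())


def _resolve_geometry(spec: PhantomSpec) -> dict:
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    m = min(spec.grid_shape)
    center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])

    j = spec.geometry_jitter
    r_head = _jittered(rng, spec.head_radius_frac * m, j)
    t_csf = _jittered(rng, spec.csf_rim_voxels, j)
    t_gm = _jittered(rng, spec.gm_shell_voxels, j)
    r_gm = r_head - t_csf
    r_wm = r_gm - t_gm
    r_vent = spec.ventricle_radius_frac * m
    r_eye = max(2.0, spec.eye_radius_frac * m)

    # Eyes sit antero-laterally (45 deg in the x-y plane), pushed as far
    # from the head as the grid allows so PSF blur from the 140 mM vitreous
    # cannot reach brain voxels.
    half = (min(nx, ny) - 1) / 2
    d_eye = math.sqrt(2.0) * (half - r_eye - 1.0)
    u = 1.0 / math.sqrt(2.0)
    eye_centers = [
        center + d_eye * np.array([+u, u, 0.0]),
        center + d_eye * np.array([-u, u, 0.0]),
    ]
    eye_gap = d_eye - r_eye - r_head

    problems = []
    if r_wm - r_vent < 2.0:
        problems.append("white-matter shell thinner than 2 voxels")
    if r_vent < 1.0:
        problems.append("ventricle smaller than 1 voxel")
    if eye_gap < 1.0:
        problems.append("no room for vitreous spheres outside the head")

    deep_center = None
    r_deep = 0.2 * r_wm
    if spec.deep_gm_nucleus and r_deep >= 1.5:
        deep_center = center + np.array([0.0, -0.55 * r_wm, 0.0])
        if 0.55 * r_wm - r_deep <= r_vent:
            deep_center = None  # would touch the ventricle; omit on tiny grids

    lesion_center = None
    r_lesion = 0.0
    if spec.lesion_fraction > 0:
        r_lesion = r_head * spec.lesion_fraction ** (1.0 / 3.0)
        if r_lesion > 0.35 * r_wm:
            problems.append("lesion_fraction too large for the white-matter core")
        else:
            lesion_center = center + np.array([-0.55 * r_wm, 0.0, 0.0])

    if problems:
        raise SizingError(
            f"grid {spec.grid_shape} too small for the phantom geometry: "
            + "; ".join(problems)
        )

    return {
        "center": center,
        "r_head": r_head,
        "r_gm": r_gm,
        "r_wm": r_wm,
        "r_vent": r_vent,
        "r_eye": r_eye,
        "eye_centers": eye_centers,
        "deep_center": deep_center,
        "r_deep": r_deep,
        "lesion_center": lesion_center,
        "r_lesion": r_lesion,
    }


def _axis_coords(n: int, factor: int) -> np.ndarray:
    """Super-sampled sub-voxel center coordinates along one axis."""
    offsets = (np.arange(factor) + 0.5) / factor - 0.5
    return (np.arange(n)[:, None] + offsets[None, :]).reshape(-1)


def _dist2(xs, ys, zs, c) -> np.ndarray:
    return (
        (xs - c[0])[:, None, None] ** 2
        + (ys - c[1])[None, :, None] ** 2
        + (zs - c[2])[None, None, :] ** 2
    )


def _box_average(arr: np.ndarray, shape, factor: int) -> np.ndarray:
    nx, ny, nz = shape
    return arr.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Construct a concentric-shell head phantom from a validated spec.

    The geometry yields pure-GM, pure-WM, pure-CSF and mixed-fraction voxels;
    fractions sum to exactly 1 inside the head and 0 in the background, and
    the ground-truth TSC equals the three-compartment mixture everywhere
    outside the vitreous spheres.
    """
    geom = _resolve_geometry(spec)
    shape = spec.grid_shape
    f = SUPERSAMPLE

    xs = _axis_coords(shape[0], f)
    ys = _axis_coords(shape[1], f)
    zs = _axis_coords(shape[2], f)

    r2 = _dist2(xs, ys, zs, geom["center"])
    in_head = r2 <= geom["r_head"] ** 2
    in_gm_out = r2 <= geom["r_gm"] ** 2
    in_wm_out = r2 <= geom["r_wm"] ** 2
    in_vent = r2 <= geom["r_vent"] ** 2
    del r2

    if geom["deep_center"] is not None:
        in_deep = _dist2(xs, ys, zs, geom["deep_center"]) <= geom["r_deep"] ** 2
    else:
        in_deep = np.zeros(in_head.shape, dtype=bool)

    csf_sub = (in_head & ~in_gm_out) | in_vent
    gm_sub = (in_gm_out & ~in_wm_out) | in_deep
    wm_sub = in_wm_out & ~in_vent & ~in_deep
    vit_sub = np.zeros(in_head.shape, dtype=bool)
    for c in geom["eye_centers"]:
        vit_sub |= _dist2(xs, ys, zs, c) <= geom["r_eye"] ** 2
    del in_head, in_gm_out, in_wm_out, in_vent, in_deep

    f_gm = _box_average(gm_sub, shape, f)
    f_wm = _box_average(wm_sub, shape, f)
    f_csf = _box_average(csf_sub, shape, f)
    f_vit = _box_average(vit_sub, shape, f)
    del gm_sub, wm_sub, csf_sub, vit_sub

    meta = dict(voxel_size=spec.voxel_size)
    fractions = TissueFractionMaps(
        VoxelGrid(f_gm, **meta), VoxelGrid(f_wm, **meta), VoxelGrid(f_csf, **meta)
    )

    truth = (
        spec.c_gm * f_gm
        + spec.c_wm * f_wm
        + spec.c_csf * f_csf
        + spec.c_vitreous * f_vit
    )

    # Pure vitreous voxels only, so the reference mean equals c_vitreous
    # exactly in a blur-free acquisition.
    vitreous_mask = f_vit >= 1.0 - 1e-12
    tissue_sum = f_gm + f_wm + f_csf
    head_mask = tissue_sum >= 1.0 - 1e-9

    # Background (noise-reference) voxels: zero tissue, well clear of both
    # the head and the eyes so PSF blur cannot deposit signal there.
    margin = 5.0
    vr2 = _dist2(np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
                 geom["center"])
    far = vr2 > (geom["r_head"] + margin) ** 2
    for c in geom["eye_centers"]:
        far &= (
            _dist2(np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), c)
            > (geom["r_eye"] + margin) ** 2
        )
    background_mask = far & (tissue_sum == 0) & (f_vit == 0)

    # ROI labels from voxel-center geometry (disjoint by construction)
    vr = np.sqrt(vr2)
    labels = np.zeros(shape, dtype=np.int16)
    labels[(vr <= geom["r_gm"]) & (vr > geom["r_wm"])] = ROI_CORTICAL_GM
    labels[(vr <= geom["r_wm"]) & (vr > geom["r_vent"])] = ROI_GLOBAL_WM
    if geom["deep_center"] is not None:
        dr2 = _dist2(np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
                     geom["deep_center"])
        labels[dr2 <= geom["r_deep"] ** 2] = ROI_DEEP_GM

    lesion = np.zeros(shape, dtype=bool)
    if geom["lesion_center"] is not None:
        lr2 = _dist2(np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
                     geom["lesion_center"])
        lesion = lr2 <= geom["r_lesion"] ** 2

    geometry = {
        k: (v.tolist() if isinstance(v, np.ndarray) else
            [c.tolist() for c in v] if k == "eye_centers" else v)
        for k, v in geom.items()
    }
    if geometry["deep_center"] is not None:
        geometry["deep_center"] = list(geometry["deep_center"])
    if geometry["lesion_center"] is not None:
        geometry["lesion_center"] = list(geometry["lesion_center"])

    return Phantom(
        spec=spec,
        fractions=fractions,
        truth_tsc=VoxelGrid(truth, **meta),
        vitreous_mask=VoxelGrid(vitreous_mask, **meta),
        background_mask=VoxelGrid(background_mask, **meta),
        lesion_mask=VoxelGrid(lesion, **meta),
        roi_labels=VoxelGrid(labels, **meta),
        head_mask=VoxelGrid(head_mask, **meta),
        geometry=geometry,
    )


def two_compartment_tsc(f_intra: float, c_intra: float, c_extra: float) -> float:
    """Volume-weighted two-compartment TSC.

    TSC is the volume-weighted average of the intra- and extracellular
    sodium concentrations: with intracellular volume fraction ``f_intra`` at
    ``c_intra`` mM and the remainder extracellular at ``c_extra`` mM,

        TSC = f_intra * c_intra + (1 - f_intra) * c_extra.

    Under normal conditions (f = 0.80, 15 mM intra, 140 mM extra) this gives
    ~40 mM; cytotoxic swelling to f = 0.85 with 20 mM intracellular gives
    38 mM, illustrating how swelling can *lower* TSC even as intracellular
    sodium rises.
    """
    if not 0.0 <= f_intra <= 1.0:
        raise DomainError(f"f_intra must be in [0, 1], got {f_intra}")
    return f_intra * c_intra + (1.0 - f_intra) * c_extra


def simulate_acquisition(
    phantom: Phantom,
    *,
    seed: int,
    psf_fwhm: float | None = None,
    noise_sd: float | None = None,
    gain: float = 1.0,
) -> VoxelGrid:
    """Forward-model a spin-density-weighted sodium acquisition.

    signal = gain * (truth_tsc convolved with the PSF) + N(0, noise_sd).

    ``psf_fwhm`` / ``noise_sd`` default to the phantom spec's values; a FWHM
    of 0 skips the blur entirely (identity forward model at unit gain and
    zero noise).
    """
    if psf_fwhm is None:
        psf_fwhm = phantom.spec.psf_fwhm
    if noise_sd is None:
        noise_sd = phantom.spec.noise_sd
    if gain <= 0:
        raise DomainError(f"gain must be > 0, got {gain}")
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd}")
    if psf_fwhm < 0:
        raise DomainError(f"psf_fwhm must be >= 0, got {psf_fwhm}")

    truth = phantom.truth_tsc.data
    blurred = truth if psf_fwhm == 0 else convolve_volume(truth, gaussian_psf_kernel(psf_fwhm))
    signal = gain * blurred
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return phantom.truth_tsc.with_data(signal)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

BTACT_SUBTESTS = (
    "btact_word_list",
    "btact_delayed_recall",
    "btact_backward_digit",
    "btact_category_fluency",
    "btact_number_series",
    "btact_backward_counting",
)


@dataclass(frozen=True, kw_only=True)
class CohortSpec:
    """Parameters of a simulated patient/control cohort.

    Group means/SDs default to the mild-TBI study values (24 patients with
    GM TSC ~ N(34.4, 2.1) and WM ~ N(30.0, 3.2); 19 controls with GM ~
    N(37.9, 1.4) and WM ~ N(31.6, 1.6)).  ``outcome_association`` is the
    target Spearman correlation between patient GM TSC and the cognitive
    composite z-score, realized through a Gaussian copula; the default 0.55
    matches the strongest reported TSC-cognition association.
    """

    seed: int
    n_patients: int = 24
    n_controls: int = 19
    gm_mean_patients: float = 34.4
    gm_sd_patients: float = 2.1
    wm_mean_patients: float = 30.0
    wm_sd_patients: float = 3.2
    gm_mean_controls: float = 37.9
    gm_sd_controls: float = 1.4
    wm_mean_controls: float = 31.6
    wm_sd_controls: float = 1.6
    outcome_association: float = 0.55
    composite_mean: float = -0.35
    composite_sd: float = 0.67
    days_since_injury_range: tuple = (5, 53)
    recovered_fraction: float = 0.30

    def __post_init__(self):
        if self.n_patients < 2 or self.n_controls < 2:
            raise DomainError("group sizes must be >= 2")
        for name in ("gm_sd_patients", "wm_sd_patients", "gm_sd_controls",
                     "wm_sd_controls", "composite_sd"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if abs(self.outcome_association) >= 1:
            raise DomainError("outcome_association magnitude must be < 1")
        lo, hi = self.days_since_injury_range
        if lo < 0 or hi < lo:
            raise DomainError("days_since_injury_range must be 0 <= lo <= hi")


def _rpq_scores(rng, total):
    """Split an RPQ total into the standard sub-scales with mild noise."""
    n = total.shape[0]
    w = np.abs(np.array([0.56, 0.21, 0.23]) + 0.05 * rng.standard_normal((n, 3)))
    w /= w.sum(axis=1, keepdims=True)
    somatic, emotional, cognitive = (total * w[:, i] for i in range(3))
    share3 = np.clip(0.16 + 0.05 * rng.standard_normal(n), 0.0, 0.4)
    rpq3 = total * share3
    return somatic, emotional, cognitive, rpq3, total - rpq3


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a subject table with the cohort's statistical structure.

    Per-subject GM/WM TSC are drawn from each group's normal distribution.
    Within patients, the cognitive composite carries the requested Spearman
    rank association with GM TSC via a Gaussian copula (latent Pearson
    rho = 2 sin(pi * rho_s / 6)); the six BTACT subtest z-scores are built
    around the composite with per-subject mean-zero deviations, so the
    composite equals the subtest mean exactly.  GOSE is assigned from the
    composite ranking so that both recovered (GOSE 8) and non-recovered
    (< 8) patients always exist.
    """
    rng = np.random.default_rng(spec.seed)
    n_p, n_c = spec.n_patients, spec.n_controls

    rho = 2.0 * math.sin(math.pi * spec.outcome_association / 6.0)
    z_gm = rng.standard_normal(n_p)
    eps = rng.standard_normal(n_p)
    z_cog = rho * z_gm + math.sqrt(1.0 - rho**2) * eps

    gm_p = spec.gm_mean_patients + spec.gm_sd_patients * z_gm
    wm_p = spec.wm_mean_patients + spec.wm_sd_patients * (
        0.6 * z_gm + 0.8 * rng.standard_normal(n_p)
    )
    comp_p = spec.composite_mean + spec.composite_sd * z_cog

    dev = 0.8 * rng.standard_normal((n_p, len(BTACT_SUBTESTS)))
    dev -= dev.mean(axis=1, keepdims=True)
    subtests_p = comp_p[:, None] + dev

    rpq_latent = -0.5 * z_cog + math.sqrt(0.75) * rng.standard_normal(n_p)
    rpq_total_p = np.clip(22.0 + 11.5 * rpq_latent, 0.0, 64.0)
    somatic, emotional, cognitive, rpq3, rpq13 = _rpq_scores(rng, rpq_total_p)

    lo, hi = spec.days_since_injury_range
    days = rng.integers(lo, hi + 1, size=n_p).astype(float)
    age_p = np.clip(rng.normal(35.9, 12.4, n_p), 18.0, 65.0)

    # GOSE: best-composite patients recover; remainder spread over 5-7.
    n_rec = int(np.clip(round(spec.recovered_fraction * n_p), 1, n_p - 1))
    order = np.argsort(-comp_p)
    gose = np.empty(n_p, dtype=int)
    gose[order[:n_rec]] = 8
    gose[order[n_rec:]] = rng.choice([5, 6, 7], size=n_p - n_rec,
                                     p=np.array([1, 14, 4]) / 19.0)

    # Controls: normative cognition, no injury covariates, minimal symptoms.
    gm_c = rng.normal(spec.gm_mean_controls, spec.gm_sd_controls, n_c)
    wm_c = spec.wm_mean_controls + spec.wm_sd_controls * (
        0.6 * (gm_c - spec.gm_mean_controls) / spec.gm_sd_controls
        + 0.8 * rng.standard_normal(n_c)
    )
    comp_c = rng.normal(0.0, spec.composite_sd, n_c)
    dev_c = 0.8 * rng.standard_normal((n_c, len(BTACT_SUBTESTS)))
    dev_c -= dev_c.mean(axis=1, keepdims=True)
    subtests_c = comp_c[:, None] + dev_c
    rpq_total_c = np.clip(rng.normal(3.0, 3.0, n_c), 0.0, 64.0)
    somatic_c, emotional_c, cognitive_c, rpq3_c, rpq13_c = _rpq_scores(rng, rpq_total_c)
    age_c = np.clip(rng.normal(31.4, 7.5, n_c), 18.0, 65.0)

    rows = {
        "id": [f"P{i+1:02d}" for i in range(n_p)] + [f"C{i+1:02d}" for i in range(n_c)],
        "group": ["patient"] * n_p + ["control"] * n_c,
        "age": np.concatenate([age_p, age_c]),
        "days_since_injury": np.concatenate([days, np.full(n_c, np.nan)]),
        "gose": np.concatenate([gose, np.full(n_c, 8, dtype=int)]),
        "rpq_total": np.concatenate([rpq_total_p, rpq_total_c]),
        "rpq3": np.concatenate([rpq3, rpq3_c]),
        "rpq13": np.concatenate([rpq13, rpq13_c]),
        "rpq_somatic": np.concatenate([somatic, somatic_c]),
        "rpq_emotional": np.concatenate([emotional, emotional_c]),
        "rpq_cognitive": np.concatenate([cognitive, cognitive_c]),
        "btact_composite": np.concatenate([comp_p, comp_c]),
        "gm_tsc": np.concatenate([gm_p, gm_c]),
        "wm_tsc": np.concatenate([wm_p, wm_c]),
    }
    for j, name in enumerate(BTACT_SUBTESTS):
        rows[name] = np.concatenate([subtests_p[:, j], subtests_c[:, j]])
    return pd.DataFrame(rows)


def save_phantom(phantom: Phantom, outdir) -> dict:
    """Write all phantom maps as NIfTI-1 plus a JSON ground-truth sidecar.

    Returns a mapping of map name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    volumes = {
        "f_gm": phantom.fractions.gm,
        "f_wm": phantom.fractions.wm,
        "f_csf": phantom.fractions.csf,
        "truth_tsc": phantom.truth_tsc,
        "vitreous_mask": phantom.vitreous_mask,
        "background_mask": phantom.background_mask,
        "lesion_mask": phantom.lesion_mask,
        "roi_labels": phantom.roi_labels,
        "head_mask": phantom.head_mask,
    }
    paths = {}
    for name, grid in volumes.items():
        path = outdir / f"{name}.nii.gz"
        grid.save(path)
        paths[name] = str(path)
    sidecar = {"spec": asdict(phantom.spec), "geometry": phantom.geometry}
    sidecar_path = outdir / "phantom.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, default=float))
    paths["sidecar"] = str(sidecar_path)
    return paths
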