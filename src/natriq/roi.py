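"""ROI-based voxel averaging with the study's exclusion rules.

Per-region metric values are the mean over ROI voxels after a fixed filter
chain that limits the analysis to normal-appearing parenchyma:

1. lesion subtraction — manually outlined findings are removed first;
2. one-voxel erosion (for CSF-adjacent ROIs such as cortical GM and
   thalamus, flagged per region) with 6-connectivity;
3. CSF partial-volume filter — voxels with CSF fraction strictly above 0.3
   are excluded;
4. upper-outlier exclusion — a single one-sided pass removing values above
   mean + 2 * sample SD of the surviving distribution.

Outliers come last because their threshold depends on the distribution that
survives the geometric filters; the pass is applied once, not iterated.
Every summary carries a ledger of voxel counts after each stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DomainError, EmptyROIError, InputError
from .grids import VoxelGrid, as_array

__all__ = [
    "ROIDefinition",
    "ROISummary",
    "erode_one_voxel",
    "exclude_high_csf",
    "exclude_upper_outliers",
    "resample_mask_nearest",
    "roi_summary",
    "label_summaries",
]

# faces-only (6-neighbour) structuring element
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class ROIDefinition:
    name: str
    mask: VoxelGrid
    erode: bool = False
    subtract_findings: bool = True

    def __post_init__(self):
        if not as_array(self.mask).astype(bool).any():
            raise InputError(f"ROI {self.name!r}: mask is empty before filtering")


@dataclass
class ROISummary:
    """Per-ROI statistics plus the stage-by-stage exclusion ledger."""

    name: str
    mean: float
    median: float
    sd: float
    n_initial: int
    n_after_lesion: int
    n_after_erosion: int
    n_after_csf: int
    n_after_outlier: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def erode_one_voxel(mask) -> np.ndarray:
    """One-voxel morphological erosion with 6-connectivity.

    A voxel survives iff all six face-neighbours are in the mask; voxels on
    the grid boundary never survive.  The result is always a subset of the
    input, and may be empty.
    """
    m = as_array(mask).astype(bool)
    return ndimage.binary_erosion(m, structure=_STRUCT_6, border_value=0)


def exclude_high_csf(mask, f_csf, max_csf: float = 0.3) -> np.ndarray:
    """Drop mask voxels whose CSF fraction is strictly greater than max_csf."""
    if not 0 <= max_csf <= 1:
        raise DomainError(f"max_csf must be in [0, 1], got {max_csf}")
    m = as_array(mask).astype(bool)
    f = as_array(f_csf)
    if f.shape != m.shape:
        raise InputError(f"CSF map shape {f.shape} != mask shape {m.shape}")
    return m & ~(f > max_csf)


def exclude_upper_outliers(values, k: float = 2.0):
    """Single one-sided outlier pass: drop values above mean + k * sample SD.

    The threshold is computed once from the full input (sample SD, ddof=1);
    there is no lower cut and no iteration.  Returns (kept values, n_removed).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise InputError(f"outlier exclusion requires >= 2 values, got {v.size}")
    threshold = v.mean() + k * v.std(ddof=1)
    kept = v[v <= threshold]
    return kept, int(v.size - kept.size)


def resample_mask_nearest(mask, target_shape) -> np.ndarray:
    """Nearest-neighbour resampling of a mask onto a grid of another shape.

    Intended for label masks segmented at a finer resolution than the metric
    map; registration estimation itself is out of scope (grids are assumed
    axis-aligned).
    """
    m = as_array(mask)
    src = np.asarray(m.shape, dtype=float)
    tgt = np.asarray(target_shape, dtype=float)
    idx = [np.minimum((np.arange(t) + 0.5) * s / t, s - 1).astype(int)
           for s, t in zip(src, tgt)]
    return m[np.ix_(*idx)]


def roi_summary(
    metric,
    roi: ROIDefinition,
    f_csf,
    lesion_mask=None,
    max_csf: float = 0.3,
    outlier_k: float = 2.0,
) -> ROISummary:
    """Voxel statistics for one ROI after the full filter chain.

    Filter order: lesion subtraction -> erosion (if flagged) -> CSF-fraction
    filter -> upper-outlier exclusion.  Raises :class:`EmptyROIError` naming
    the stage that removed the last voxel.  Statistics (mean, median, sample
    SD) are computed on the surviving voxel values.
    """
    met = np.asarray(as_array(metric), dtype=float)
    mask = as_array(roi.mask).astype(bool)
    if mask.shape != met.shape:
        raise InputError(
            f"ROI {roi.name!r}: mask shape {mask.shape} != metric shape {met.shape}"
        )
    n_initial = int(mask.sum())

    def _check(stage, m):
        if not m.any():
            raise EmptyROIError(f"ROI {roi.name!r} emptied at stage {stage!r}")

    if roi.subtract_findings and lesion_mask is not None:
        les = as_array(lesion_mask).astype(bool)
        if les.shape != mask.shape:
            raise InputError("lesion mask shape does not match the ROI grid")
        mask = mask & ~les
    _check("lesion", mask)
    n_lesion = int(mask.sum())

    if roi.erode:
        mask = erode_one_voxel(mask)
    _check("erosion", mask)
    n_erosion = int(mask.sum())

    mask = exclude_high_csf(mask, f_csf, max_csf)
    _check("csf", mask)
    n_csf = int(mask.sum())

    values = met[mask]
    if values.size >= 2:
        values, _removed = exclude_upper_outliers(values, k=outlier_k)
    if values.size == 0:
        raise EmptyROIError(f"ROI {roi.name!r} emptied at stage 'outlier'")
    n_outlier = int(values.size)

    return ROISummary(
        name=roi.name,
        mean=float(values.mean()),
        median=float(np.median(values)),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        n_initial=n_initial,
        n_after_lesion=n_lesion,
        n_after_erosion=n_erosion,
        n_after_csf=n_csf,
        n_after_outlier=n_outlier,
    )


def label_summaries(
    metric,
    labels,
    f_csf,
    lesion_mask=None,
    max_csf: float = 0.3,
    outlier_k: float = 2.0,
    roi_names: dict | None = None,
    eroded_labels: tuple = (),
) -> list:
    """Run :func:`roi_summary` for every non-zero label of a label volume.

    ``eroded_labels`` lists the label codes of CSF-adjacent ROIs that get
    the one-voxel erosion (cortical GM and thalamus in the study).
    """
    lab = as_array(labels)
    carrier = labels if isinstance(labels, VoxelGrid) else VoxelGrid(lab)
    out = []
    for code in sorted(int(c) for c in np.unique(lab) if c != 0):
        name = (roi_names or {}).get(code, f"roi_{code}")
        roi = ROIDefinition(
            name=name,
            mask=carrier.with_data(lab == code),
            erode=code in eroded_labels,
        )
        out.append(
            roi_summary(metric, roi, f_csf, lesion_mask=lesion_mask,
                        max_csf=max_csf, outlier_k=outlier_k)
        )
    return out
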