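"""Two-point internal-reference calibration of sodium signal to TSC (mM).

The sodium coil geometry precludes external reference phantoms, so the
signal-intensity image is calibrated against two internal references: the
vitreous humour of the eyes (sodium concentration taken as 140 mM) and the
background noise (0 mM).  The calibration is the straight line through the
two reference means; applying it voxelwise converts signal to concentration.
No relaxation-time (T1/T2) correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCalibrationError, InputError
from .grids import VoxelGrid, as_array

__all__ = ["CalibrationModel", "fit_two_point", "apply_calibration"]


@dataclass(frozen=True)
class CalibrationModel:
    """Affine signal-to-concentration map c = slope * s + intercept.

    By construction the model returns 0 mM at the noise reference signal and
    ``c_vitreous`` at the vitreous reference signal.
    """

    slope: float
    intercept: float
    ref_signal_noise: float
    ref_signal_vitreous: float
    c_vitreous: float
    source_shape: tuple | None = None

    def __call__(self, signal):
        return self.slope * np.asarray(signal, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "ref_signal_noise": self.ref_signal_noise,
            "ref_signal_vitreous": self.ref_signal_vitreous,
            "c_vitreous": self.c_vitreous,
        }


def fit_two_point(
    signal,
    noise_mask,
    vitreous_mask,
    c_vitreous: float = 140.0,
    statistic: str = "mean",
) -> CalibrationModel:
    """Fit the calibration line through the two reference-region statistics.

    slope = c_vitreous / (ref_vitreous - ref_noise); intercept maps the
    noise reference to exactly 0 mM.  Both eyes' voxels are expected to be
    pooled into one vitreous mask.  ``statistic`` is "mean" (default) or
    "median".
    """
    sig = np.asarray(as_array(signal), dtype=float)
    n_mask = as_array(noise_mask).astype(bool)
    v_mask = as_array(vitreous_mask).astype(bool)
    for name, m in (("noise", n_mask), ("vitreous", v_mask)):
        if m.shape != sig.shape:
            raise InputError(f"{name} mask shape {m.shape} != signal shape {sig.shape}")
        if not m.any():
            raise InputError(f"{name} mask is empty")

    reducer = {"mean": np.mean, "median": np.median}.get(statistic)
    if reducer is None:
        raise InputError(f"unknown reference statistic {statistic!r}")
    ref_noise = float(reducer(sig[n_mask]))
    ref_vit = float(reducer(sig[v_mask]))
    if ref_vit <= ref_noise:
        raise DegenerateCalibrationError(
            f"vitreous reference ({ref_vit:g}) must exceed noise reference "
            f"({ref_noise:g})"
        )
    slope = c_vitreous / (ref_vit - ref_noise)
    return CalibrationModel(
        slope=slope,
        intercept=-slope * ref_noise,
        ref_signal_noise=ref_noise,
        ref_signal_vitreous=ref_vit,
        c_vitreous=float(c_vitreous),
        source_shape=sig.shape,
    )


def apply_calibration(signal, model: CalibrationModel) -> VoxelGrid:
    """Voxelwise affine conversion of a signal volume to a TSC map in mM.

    Negative outputs are preserved — they are diagnostic of noise or
    calibration problems, not clipped away.
    """
    if isinstance(signal, VoxelGrid):
        carrier, sig = signal, signal.data
    else:
        sig = np.asarray(signal, dtype=float)
        carrier = VoxelGrid(sig)
    if model.source_shape is not None and tuple(sig.shape) != tuple(model.source_shape):
        raise InputError(
            f"signal shape {sig.shape} does not match calibration provenance "
            f"shape {tuple(model.source_shape)}"
        )
    return carrier.with_data(model(sig))
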