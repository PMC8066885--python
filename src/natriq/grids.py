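"""Voxel-grid containers and NIfTI-1 I/O.

A :class:`VoxelGrid` is the common carrier for every 3D volume the package
handles: signal-intensity sodium images, total-sodium-concentration (TSC)
maps in mM, tissue-fraction maps in [0, 1], and binary or integer-label
masks.  It is a thin wrapper around a numpy array plus voxel-size metadata
and an optional affine; all numerics operate on ``.data`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import InputError

__all__ = ["VoxelGrid", "TissueFractionMaps", "as_array"]


def as_array(volume) -> np.ndarray:
    """Return the underlying array of a VoxelGrid, or pass an array through."""
    if isinstance(volume, VoxelGrid):
        return volume.data
    return np.asarray(volume)


@dataclass
class VoxelGrid:
    """A 3D scalar volume with voxel-size metadata.

    Parameters
    ----------
    data
        3D array.  dtype is preserved (bool for masks, float for maps).
    voxel_size
        Edge lengths of a voxel in mm.
    affine
        Optional 4x4 voxel-to-world affine.  Defaults to a diagonal affine
        built from ``voxel_size``.
    """

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InputError(f"VoxelGrid requires a 3D array, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """A new grid sharing this grid's geometry metadata."""
        return VoxelGrid(np.asarray(data), self.voxel_size, self.affine.copy())

    def save(self, path) -> None:
        """Write the volume as NIfTI-1 (float32 for maps, uint8 for masks)."""
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        elif np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        img = nib.Nifti1Image(data, self.affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, zooms, np.asarray(img.affine))


@dataclass
class TissueFractionMaps:
    """Co-registered GM/WM/CSF fraction maps — the regressors of the
    three-compartment mixture model TSC = C_GM f_GM + C_WM f_WM + C_CSF f_CSF."""

    gm: VoxelGrid
    wm: VoxelGrid
    csf: VoxelGrid

    def __post_init__(self):
        shapes = {self.gm.shape, self.wm.shape, self.csf.shape}
        if len(shapes) != 1:
            raise InputError(f"fraction maps must share one grid shape, got {shapes}")
        for name, g in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            lo, hi = float(np.min(g.data)), float(np.max(g.data))
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise InputError(f"{name} fractions outside [0,1]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple:
        return self.gm.shape

    def sum(self) -> np.ndarray:
        """Per-voxel tissue-fraction sum f_GM + f_WM + f_CSF."""
        return self.gm.data + self.wm.data + self.csf.data

    def map_each(self, fn) -> "TissueFractionMaps":
        """Apply ``fn`` (array -> array) to each map, keeping metadata."""
        return TissueFractionMaps(
            self.gm.with_data(fn(self.gm.data)),
            self.wm.with_data(fn(self.wm.data)),
            self.csf.with_data(fn(self.csf.data)),
        )
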