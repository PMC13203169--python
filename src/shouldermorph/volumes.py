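"""Voxel grid containers with physical spacing, plus NIfTI round-tripping."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VoxelVolume", "LabelVolume", "save_nifti", "load_nifti", "load_label_nifti"]


@dataclass
class VoxelVolume:
    """A 3-D scalar image with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume(VoxelVolume):
    """Integer class map sharing a grid with a VoxelVolume."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")

    def classes(self) -> np.ndarray:
        return np.unique(self.data)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(vol: VoxelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> VoxelVolume:
    img = nib.load(str(path))
    return VoxelVolume(np.asarray(img.dataobj), tuple(img.header.get_zooms()[:3]))


def load_label_nifti(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return LabelVolume(np.rint(data).astype(np.int16), tuple(img.header.get_zooms()[:3]))
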