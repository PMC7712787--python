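"""3D scalar volumes with physical voxel spacing.

A :class:`VoxelVolume` is the common container for every image the pipeline
touches: PET standardized-uptake-value (SUV) maps, diffusion-weighted MR
signal at a given b-value, and apparent-diffusion-coefficient (ADC) maps.
Axis convention: ``values[i, j, k]`` with the last axis taken as the axial
(slice) direction; ``spacing`` is millimetres per voxel along each axis.

ADC volumes store raw mm^2/s (a typical tissue value is ~1e-3); reporting
functions convert to the conventional 1e-3 mm^2/s unit. Invalid ADC voxels
(sub-floor signal) are stored as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

MODALITIES = ("SUV", "DWI_b0", "DWI_b800", "ADC")


@dataclass
class VoxelVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values. SUV and DWI volumes must be non-negative; ADC volumes
        may contain NaN marking invalid voxels.
    spacing : tuple of float
        Voxel edge lengths in mm, one per axis, all positive.
    modality : str
        One of ``SUV``, ``DWI_b0``, ``DWI_b800``, ``ADC``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "SUV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"values must be a non-empty 3D array, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.modality != "ADC":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and finite.min() < 0:
                raise ValueError(f"{self.modality} volumes must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3."""
        return math.prod(self.spacing)

    def save_nifti(self, path: str) -> None:
        """Write as NIfTI-1 with the spacing encoded in the affine."""
        affine = np.diag([*self.spacing, 1.0])
        img = nib.Nifti1Image(self.values.astype(np.float32), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, path)


def load_nifti(path: str, modality: str) -> VoxelVolume:
    """Read a NIfTI-1 volume written by :meth:`VoxelVolume.save_nifti`."""
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(np.asarray(img.dataobj, dtype=float), spacing, modality)
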