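"""Lesion cropping and rotation augmentation for the CNN classifier.

Each patient contributes one 64x64 crop per modality/timepoint (PET0, PET1
from the SUV volumes; MRI0, MRI1 from the computed ADC maps), taken at the
axial slice with the largest lesion cross-section: a square window around
the lesion's tight in-plane bounding box with a 20% margin, bilinearly
resampled to 64x64 and min-max normalized to [0, 1] per image. The
per-image normalization removes absolute-intensity shortcuts, so the
classifier has to rely on morphology and texture.

Class imbalance is countered by rotating each responder crop seven times in
45-degree increments (45..315), yielding 7 extra images per responder —
6 responders become 48 responder images next to 50 non-responder ones.
Rotation happens after resize/normalization; corners uncovered by the
rotated support are zero-filled. Multiples of 90 degrees are pure axis
permutations with no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as sk_resize
from skimage.transform import rotate as sk_rotate

from .phantom import PatientStudy
from .quant import EllipsoidVOI, QuantConfig, adc_map, default_regions, largest_cross_section
from .volume import VoxelVolume

CROP_SIZE = 64
MODALITY_TIMEPOINTS = ("PET0", "PET1", "MRI0", "MRI1")
ROTATION_STEP_DEG = 45.0
N_ROTATIONS = 7


@dataclass
class LesionCrop:
    """A 64x64 lesion image with its label and provenance."""

    pixels: np.ndarray
    patient_id: str
    modality_timepoint: str
    responder: bool
    provenance: str = "original"  # or "rotation_{k}x45deg", k in 1..7

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"crop must be {CROP_SIZE}x{CROP_SIZE}, got {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("crop contains non-finite pixels")
        if self.modality_timepoint not in MODALITY_TIMEPOINTS:
            raise ValueError(f"unknown modality_timepoint {self.modality_timepoint!r}")


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def crop_lesion(
    volume: VoxelVolume,
    region: EllipsoidVOI,
    modality_timepoint: str,
    responder: bool = False,
    patient_id: str = "",
    suv_threshold: float | None = None,
) -> LesionCrop:
    """Crop the lesion at its largest axial cross-section.

    The square window side is the larger side of the in-plane bounding box
    of the lesion mask plus a 20% margin (at least 4 pixels); out-of-grid
    parts of the window are zero-padded before the bilinear resize to 64x64.
    """
    z = largest_cross_section(volume, region, suv_threshold)
    mask3 = region.mask(volume)
    plane_mask = mask3[:, :, z]
    if suv_threshold is not None:
        thr_mask = plane_mask & (volume.values[:, :, z] >= suv_threshold)
        if thr_mask.any():
            plane_mask = thr_mask
    if not plane_mask.any():
        raise ValueError("lesion is empty on every axial slice")
    plane = np.nan_to_num(volume.values[:, :, z], nan=0.0)

    rows = np.flatnonzero(plane_mask.any(axis=1))
    cols = np.flatnonzero(plane_mask.any(axis=0))
    r0, r1 = rows[0], rows[-1]
    c0, c1 = cols[0], cols[-1]
    side = max(int(np.ceil(1.2 * max(r1 - r0 + 1, c1 - c0 + 1))), 4)
    cr, cc = (r0 + r1) // 2, (c0 + c1) // 2
    half = side // 2
    patch = np.zeros((side, side))
    rs, re = cr - half, cr - half + side
    cs, ce = cc - half, cc - half + side
    src = plane[max(rs, 0):re, max(cs, 0):ce]
    patch[max(rs, 0) - rs:max(rs, 0) - rs + src.shape[0],
          max(cs, 0) - cs:max(cs, 0) - cs + src.shape[1]] = src

    if side == CROP_SIZE:
        resized = patch
    else:
        resized = sk_resize(patch, (CROP_SIZE, CROP_SIZE), order=1,
                            anti_aliasing=False, preserve_range=True)
    return LesionCrop(
        pixels=_minmax(resized),
        patient_id=patient_id,
        modality_timepoint=modality_timepoint,
        responder=responder,
    )


def rotate_crop(pixels: np.ndarray, k: int) -> np.ndarray:
    """Rotate a crop by ``k * 45`` degrees about the image center.

    Even ``k`` (multiples of 90 degrees) use exact axis permutations; odd
    ``k`` use bilinear interpolation with zero fill outside the support.
    """
    if k % 2 == 0:
        return np.rot90(pixels, k // 2).copy()
    return sk_rotate(pixels, angle=ROTATION_STEP_DEG * k, resize=False,
                     order=1, mode="constant", cval=0.0, preserve_range=True)


def augment_rotations(crops: list[LesionCrop]) -> list[LesionCrop]:
    """Produce the seven 45-degree rotations of each responder crop.

    Only responder originals may be augmented (the augmentation exists to
    rebalance the responder class); the originals are not included in the
    returned list.
    """
    out = []
    for crop in crops:
        if not crop.responder:
            raise ValueError("rotation augmentation is applied to responder crops only")
        for k in range(1, N_ROTATIONS + 1):
            out.append(LesionCrop(
                pixels=rotate_crop(crop.pixels, k),
                patient_id=crop.patient_id,
                modality_timepoint=crop.modality_timepoint,
                responder=True,
                provenance=f"rotation_{k}x45deg",
            ))
    return out


def build_dataset(
    cohort: list[PatientStudy],
    modality_timepoint: str,
    augment: bool,
    config: QuantConfig | None = None,
) -> list[LesionCrop]:
    """One original crop per patient, plus responder rotations if ``augment``.

    For the study-sized cohort (6 responders, 50 non-responders) this yields
    56 crops unaugmented and 98 crops (48 responder-labelled) augmented.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if modality_timepoint not in MODALITY_TIMEPOINTS:
        raise ValueError(f"unknown modality_timepoint {modality_timepoint!r}")
    config = config or QuantConfig()
    interim = modality_timepoint in ("PET1", "MRI1")
    crops = []
    for study in cohort:
        voi, _ = default_regions(study, interim=interim)
        if modality_timepoint.startswith("PET"):
            volume = study.pet_interim if interim else study.pet_baseline
            thr = config.suv_threshold
        else:
            pair = study.dwi_interim if interim else study.dwi_baseline
            volume = adc_map(*pair, config)
            thr = None
        crops.append(crop_lesion(volume, voi, modality_timepoint,
                                 responder=study.true_response,
                                 patient_id=study.patient_id,
                                 suv_threshold=thr))
    if augment:
        responders = [c for c in crops if c.responder]
        crops = crops + augment_rotations(responders)
    return crops
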