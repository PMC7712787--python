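"""Conventional PET/MRI parameter extraction.

Implements the twelve per-patient parameters used to grade early response to
neoadjuvant chemotherapy:

* ``SUV0/SUV1`` — maximum standardized uptake value inside an ellipsoid
  volume of interest (VOI), baseline / interim;
* ``MTV0/MTV1`` — metabolic tumor volume: total volume (mL) of in-VOI voxels
  at or above the SUV threshold (2.5 by default);
* ``TLG0/TLG1`` — total lesion glycolysis: MTV times the mean SUV of the
  qualifying voxels;
* ``ADC0/ADC1`` — mean apparent diffusion coefficient inside a circular ROI
  on the axial ADC map, in 1e-3 mm^2/s;
* the four percent changes ``(interim - baseline) * 100 / baseline``, which
  are undefined (missing) when the baseline is zero.

A voxel belongs to a VOI or ROI iff its *center* satisfies the region
inequality; the SUV threshold is inclusive (>= 2.5). Both conventions are
pinned by tests against exhaustive-enumeration oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import PatientStudy
from .volume import VoxelVolume


@dataclass
class EllipsoidVOI:
    """Ellipsoid volume of interest: center voxel index + semi-axes in mm."""

    center: tuple[int, int, int]
    radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"VOI radii must be positive, got {self.radii}")

    def mask(self, volume: VoxelVolume) -> np.ndarray:
        """Boolean voxel-membership mask on the volume's grid."""
        axes = [
            ((np.arange(n) - c) * s / r) ** 2
            for n, s, c, r in zip(volume.shape, volume.spacing, self.center, self.radii)
        ]
        rho2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
        return rho2 <= 1.0


@dataclass
class CircleROI:
    """Circular ROI on one axial slice: in-plane center (voxel coords) + radius in mm."""

    slice_index: int
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"ROI radius must be positive, got {self.radius}")

    def mask(self, volume: VoxelVolume) -> np.ndarray:
        """In-plane boolean membership mask for the ROI's slice."""
        nx, ny, _ = volume.shape
        sx, sy, _ = volume.spacing
        dx2 = ((np.arange(nx) - self.center[0]) * sx) ** 2
        dy2 = ((np.arange(ny) - self.center[1]) * sy) ** 2
        return dx2[:, None] + dy2[None, :] <= self.radius**2


@dataclass
class QuantConfig:
    suv_threshold: float = 2.5
    b_low: float = 0.0
    b_high: float = 800.0
    signal_floor: float = 1.0  # DWI signal below this is treated as invalid

    def __post_init__(self) -> None:
        if self.suv_threshold <= 0:
            raise ValueError("suv_threshold must be positive")
        if not self.b_high > self.b_low >= 0:
            raise ValueError("need b_high > b_low >= 0")


@dataclass
class ParameterRecord:
    """The twelve conventional parameters of one patient.

    Percent changes are ``None`` when their baseline value is zero (the
    defining ratio is undefined there).
    """

    patient_id: str
    suv0: float
    suv1: float
    mtv0: float
    mtv1: float
    tlg0: float
    tlg1: float
    adc0: float
    adc1: float
    dsuv: float | None
    dmtv: float | None
    dtlg: float | None
    dadc: float | None


def _voi_values(volume: VoxelVolume, voi: EllipsoidVOI) -> np.ndarray:
    mask = voi.mask(volume)
    if not mask.any():
        raise ValueError("VOI does not intersect the image grid")
    return volume.values[mask]


def suv_max(volume: VoxelVolume, voi: EllipsoidVOI) -> float:
    """Maximum SUV among voxels whose centers lie inside the VOI."""
    return float(_voi_values(volume, voi).max())


def metabolic_tumor_volume(volume: VoxelVolume, voi: EllipsoidVOI,
                           config: QuantConfig | None = None) -> float:
    """MTV in mL: qualifying in-VOI voxel count times voxel volume."""
    config = config or QuantConfig()
    vals = _voi_values(volume, voi)
    n = int((vals >= config.suv_threshold).sum())
    return n * volume.voxel_volume_mm3 / 1000.0


def total_lesion_glycolysis(volume: VoxelVolume, voi: EllipsoidVOI,
                            config: QuantConfig | None = None) -> float:
    """TLG in mL*SUV: MTV times mean SUV over the qualifying voxels; 0 if MTV is 0."""
    config = config or QuantConfig()
    vals = _voi_values(volume, voi)
    qualifying = vals[vals >= config.suv_threshold]
    if qualifying.size == 0:
        return 0.0
    mtv = qualifying.size * volume.voxel_volume_mm3 / 1000.0
    return float(mtv * qualifying.mean())


def adc_map(b0: VoxelVolume, bhigh: VoxelVolume, config: QuantConfig | None = None) -> VoxelVolume:
    """Two-point ADC map: ``ln(S_b0 / S_bhigh) / (b_high - b_low)`` per voxel.

    Voxels where either signal falls below ``signal_floor`` are invalid (NaN,
    excluded from ROI means); noise-induced negative ADC clamps to 0.
    """
    config = config or QuantConfig()
    if b0.shape != bhigh.shape or b0.spacing != bhigh.spacing:
        raise ValueError("b0 and bhigh volumes must share grid shape and spacing")
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(b0.values / bhigh.values) / (config.b_high - config.b_low)
    invalid = (b0.values < config.signal_floor) | (bhigh.values < config.signal_floor)
    adc = np.maximum(adc, 0.0)
    adc[invalid] = np.nan
    return VoxelVolume(adc, b0.spacing, "ADC")


def roi_mean_adc(adc: VoxelVolume, roi: CircleROI) -> float:
    """Mean ADC over valid in-circle voxels, in 1e-3 mm^2/s."""
    if not 0 <= roi.slice_index < adc.shape[2]:
        raise ValueError(f"slice_index {roi.slice_index} outside the volume")
    plane = adc.values[:, :, roi.slice_index]
    mask = roi.mask(adc)
    vals = plane[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid ADC voxel inside the ROI")
    return float(vals.mean() * 1e3)


def percent_change(baseline: float, interim: float) -> float | None:
    """``(interim - baseline) * 100 / baseline``; None when baseline is 0."""
    if baseline < 0 or interim < 0:
        raise ValueError("percent_change expects non-negative inputs")
    if baseline == 0:
        return None
    return (interim - baseline) * 100.0 / baseline


def largest_cross_section(volume: VoxelVolume, voi: EllipsoidVOI,
                          suv_threshold: float | None = None) -> int:
    """Axial slice index with the largest lesion cross-section.

    Counts in-VOI voxels at or above ``suv_threshold`` when given (PET); the
    in-VOI area otherwise (ADC). Falls back to the plain VOI area when no
    voxel reaches the threshold on any slice. Ties break to the lowest index.
    """
    mask = voi.mask(volume)
    if not mask.any():
        raise ValueError("VOI does not intersect the image grid")
    if suv_threshold is not None:
        counts = (mask & (volume.values >= suv_threshold)).sum(axis=(0, 1))
        if counts.max() == 0:
            counts = mask.sum(axis=(0, 1))
    else:
        counts = mask.sum(axis=(0, 1))
    return int(np.argmax(counts))


def extract_parameters(
    study: PatientStudy,
    voi0: EllipsoidVOI,
    voi1: EllipsoidVOI,
    roi0: CircleROI,
    roi1: CircleROI,
    config: QuantConfig | None = None,
) -> ParameterRecord:
    """Compute all twelve conventional parameters for one patient."""
    config = config or QuantConfig()
    suv0 = suv_max(study.pet_baseline, voi0)
    suv1 = suv_max(study.pet_interim, voi1)
    mtv0 = metabolic_tumor_volume(study.pet_baseline, voi0, config)
    mtv1 = metabolic_tumor_volume(study.pet_interim, voi1, config)
    tlg0 = total_lesion_glycolysis(study.pet_baseline, voi0, config)
    tlg1 = total_lesion_glycolysis(study.pet_interim, voi1, config)
    adc0 = roi_mean_adc(adc_map(*study.dwi_baseline, config), roi0)
    adc1 = roi_mean_adc(adc_map(*study.dwi_interim, config), roi1)
    return ParameterRecord(
        patient_id=study.patient_id,
        suv0=suv0, suv1=suv1,
        mtv0=mtv0, mtv1=mtv1,
        tlg0=tlg0, tlg1=tlg1,
        adc0=adc0, adc1=adc1,
        dsuv=percent_change(suv0, suv1),
        dmtv=percent_change(mtv0, mtv1),
        dtlg=percent_change(tlg0, tlg1),
        dadc=percent_change(adc0, adc1),
    )


def default_regions(study: PatientStudy, interim: bool) -> tuple[EllipsoidVOI, CircleROI]:
    """Ground-truth VOI/ROI placement for a phantom patient.

    The VOI is the true tumor ellipsoid of the requested timepoint; the ADC
    ROI is a circle of 60% of the smaller in-plane semi-axis on the center
    slice, keeping it strictly inside the lesion.
    """
    radii = study.tumor_radii_interim if interim else study.tumor_radii
    voi = EllipsoidVOI(center=study.tumor_center, radii=radii)
    roi = CircleROI(
        slice_index=study.tumor_center[2],
        center=(float(study.tumor_center[0]), float(study.tumor_center[1])),
        radius=max(0.6 * min(radii[0], radii[1]), 1e-3),
    )
    return voi, roi


def cohort_parameters(cohort: list[PatientStudy],
                      config: QuantConfig | None = None):
    """Parameter records for a whole phantom cohort, as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for study in cohort:
        voi0, roi0 = default_regions(study, interim=False)
        voi1, roi1 = default_regions(study, interim=True)
        rec = extract_parameters(study, voi0, voi1, roi0, roi1, config)
        rows.append({k: (np.nan if v is None else v) for k, v in vars(rec).items()})
    return pd.DataFrame(rows)
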