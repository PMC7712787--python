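"""Synthetic longitudinal PET/DWI phantom cohorts with known ground truth.

The generator emulates the study design this package analyses: each patient
has a baseline and an interim (after the first chemotherapy cycle) PET SUV
volume and a baseline/interim pair of diffusion-weighted volumes at b = 0
and b = 800 s/mm^2, a Miller-Payne grade, and ER/PR/HER2 receptor flags.
Responders carry a large metabolic decline and an ADC rise between the two
timepoints; non-responders change little. The true per-patient effect sizes
(percent changes of peak SUV, tumor volume and tumor ADC) are recorded so
every downstream measurement can be checked against ground truth.

Tumors are ellipsoids on a regular voxel grid. The PET profile inside the
ellipsoid falls off quadratically from the peak at the center to 40% of the
peak at the rim, which keeps the SUVmax location unambiguous and puts the
2.5-SUV segmentation boundary inside the tumor once the peak drops far
enough. PET noise is multiplicative Gaussian (floored at zero); DWI noise is
Rician, the standard magnitude-MR model. Interim tumors shrink their radii
by the cube root of the drawn volume change and scale their peak by the
drawn SUV change, coupling volumetric and intensity effects.

Randomness: a single top-level seed; each patient uses an independent
substream keyed by patient index, so growing the cohort never reshuffles
earlier patients.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import VoxelVolume


@dataclass
class SubtypePrevalence:
    """Probability of a positive receptor, separately per response class."""

    responder: float
    nonresponder: float


# Receptor-positivity rates mirror a typical advanced-breast-cancer NAC
# cohort: responders are enriched for receptor-negative disease.
DEFAULT_PREVALENCE = {
    "ER": SubtypePrevalence(responder=1 / 6, nonresponder=24 / 49),
    "PR": SubtypePrevalence(responder=3 / 6, nonresponder=29 / 49),
    "HER2": SubtypePrevalence(responder=1 / 6, nonresponder=20 / 49),
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Distribution pairs are (mean, sd). ``baseline_suvmax_dist`` parameterizes
    a lognormal by its own mean/sd; the change distributions are normal in
    percent and are truncated so tumors stay visible (peak above background)
    and values stay physical (floors noted per field).
    """

    n_responders: int = 6
    n_nonresponders: int = 50
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_radius_range: tuple[float, float] = (8.0, 20.0)  # mm per semi-axis
    baseline_suvmax_dist: tuple[float, float] = (8.0, 3.0)  # lognormal mean/sd, floor 3.0
    responder_dsuv_dist: tuple[float, float] = (-70.0, 15.0)  # percent
    nonresponder_dsuv_dist: tuple[float, float] = (-20.0, 15.0)
    responder_dmtv_dist: tuple[float, float] = (-85.0, 10.0)  # percent volume change
    nonresponder_dmtv_dist: tuple[float, float] = (-30.0, 20.0)
    baseline_adc_dist: tuple[float, float] = (1.0, 0.15)  # 1e-3 mm^2/s, floor 0.4
    responder_dadc_dist: tuple[float, float] = (40.0, 15.0)  # percent
    nonresponder_dadc_dist: tuple[float, float] = (5.0, 15.0)
    background_suv: float = 0.3
    background_adc: float = 1.6  # 1e-3 mm^2/s, fibroglandular-like
    s0_level: float = 1000.0
    b_high: float = 800.0
    noise_sigma: float = 0.05  # relative sd for PET, fraction of s0 for DWI
    texture_flag: bool = False
    texture_amplitude: float = 0.4
    texture_smoothing: float = 1.2  # Gaussian sigma in voxels
    subtype_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    seed: int = 0

    def validate(self) -> None:
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise ValueError("patient counts must be non-negative")
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive sizes, got {self.grid_shape}")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError("tumor_radius_range must satisfy 0 < lo <= hi")
        if self.background_suv < 0 or self.noise_sigma < 0:
            raise ValueError("background_suv and noise_sigma must be non-negative")
        if self.s0_level <= 0 or self.b_high <= 0:
            raise ValueError("s0_level and b_high must be positive")


@dataclass
class PatientStudy:
    """One synthetic patient with imaging, histopathology and ground truth."""

    patient_id: str
    pet_baseline: VoxelVolume
    pet_interim: VoxelVolume
    dwi_baseline: tuple[VoxelVolume, VoxelVolume]  # (b0, b_high)
    dwi_interim: tuple[VoxelVolume, VoxelVolume]
    tumor_center: tuple[int, int, int]  # voxel index
    tumor_radii: tuple[float, float, float]  # baseline semi-axes, mm
    tumor_radii_interim: tuple[float, float, float]
    true_response: bool
    grade: int  # Miller-Payne 1..5
    er_positive: bool
    pr_positive: bool
    her2_positive: bool
    # realized (post-truncation) effect sizes, percent / absolute
    true_suv0: float = float("nan")
    true_dsuv: float = float("nan")
    true_dmtv: float = float("nan")
    true_adc0: float = float("nan")  # 1e-3 mm^2/s
    true_dadc: float = float("nan")


def _ellipsoid_rho2(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[int, int, int],
    radii: tuple[float, float, float],
) -> np.ndarray:
    """Squared normalized ellipsoid coordinate at every voxel center."""
    axes = [
        ((np.arange(n) - c) * s / r) ** 2
        for n, s, c, r in zip(grid_shape, spacing, center, radii)
    ]
    return axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]


def render_tumor_pet(
    center: tuple[int, int, int],
    radii: tuple[float, float, float],
    suv_peak: float,
    background: float,
    noise_sigma: float,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
    texture: np.ndarray | None = None,
) -> VoxelVolume:
    """Render a PET SUV volume containing one ellipsoidal tumor.

    The in-tumor profile is ``peak * (1 - 0.6 * rho^2)`` where ``rho`` is the
    normalized ellipsoid coordinate, i.e. the rim sits at 40% of the peak.
    ``texture``, if given, is a multiplicative field applied inside the tumor
    before noise. Multiplicative Gaussian noise of relative sd ``noise_sigma``
    is applied last and the result floored at zero.
    """
    if any(r <= 0 for r in radii):
        raise ValueError(f"tumor radii must be positive, got {radii}")
    if not (suv_peak > background >= 0):
        raise ValueError("need suv_peak > background >= 0")
    rho2 = _ellipsoid_rho2(grid_shape, spacing, center, radii)
    inside = rho2 <= 1.0
    values = np.full(grid_shape, background, dtype=float)
    profile = suv_peak * (1.0 - 0.6 * rho2[inside])
    if texture is not None:
        profile = profile * (1.0 + texture[inside])
    values[inside] = np.maximum(profile, 0.0)
    if noise_sigma > 0:
        values = values * (1.0 + noise_sigma * rng.standard_normal(grid_shape))
        values = np.maximum(values, 0.0)
    return VoxelVolume(values, spacing, "SUV")


def render_dwi_pair(
    adc_field: VoxelVolume,
    s0_level: float,
    b_high: float,
    noise_sigma: float,
    rng: np.random.Generator,
) -> tuple[VoxelVolume, VoxelVolume]:
    """Render a (b=0, b=b_high) DWI pair from a ground-truth ADC field.

    Signal model: ``S(b) = S0 * exp(-b * ADC)`` with ADC in mm^2/s. Noise is
    Rician with scale ``noise_sigma * s0_level``, the magnitude-image model:
    ``sqrt((S + n1)^2 + n2^2)`` with independent Gaussian n1, n2.
    """
    if adc_field.modality != "ADC":
        raise ValueError("adc_field must have modality 'ADC'")
    if np.nanmin(adc_field.values) <= 0:
        raise ValueError("adc_field must be strictly positive")
    if s0_level <= 0:
        raise ValueError("s0_level must be positive")
    if b_high <= 0:
        raise ValueError("b_high must be positive")
    shape = adc_field.shape
    s_b0 = np.full(shape, float(s0_level))
    s_bh = s0_level * np.exp(-b_high * adc_field.values)
    if noise_sigma > 0:
        scale = noise_sigma * s0_level
        s_b0 = np.hypot(s_b0 + scale * rng.standard_normal(shape), scale * rng.standard_normal(shape))
        s_bh = np.hypot(s_bh + scale * rng.standard_normal(shape), scale * rng.standard_normal(shape))
    return (
        VoxelVolume(s_b0, adc_field.spacing, "DWI_b0"),
        VoxelVolume(s_bh, adc_field.spacing, "DWI_b800"),
    )


def assign_grade(true_response: bool, rng: np.random.Generator) -> int:
    """Draw a Miller-Payne grade consistent with the latent response.

    Responders get grade 4 or 5, non-responders 1-3, uniform within the set —
    the grade boundary that defines the response classes.
    """
    if true_response:
        return int(rng.integers(4, 6))
    return int(rng.integers(1, 4))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _make_texture(
    grid_shape: tuple[int, int, int],
    amplitude: float,
    smoothing: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smoothed, unit-sd multiplicative speckle field scaled by amplitude."""
    from scipy.ndimage import gaussian_filter

    raw = rng.standard_normal(grid_shape)
    smooth = gaussian_filter(raw, sigma=smoothing)
    sd = smooth.std()
    if sd == 0:
        return np.zeros(grid_shape)
    # clip so the multiplicative factor stays positive
    return np.clip(amplitude * smooth / sd, -0.9, 0.9)


def _generate_patient(index: int, responder: bool, config: CohortConfig) -> PatientStudy:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))
    shape = tuple(int(n) for n in config.grid_shape)
    spacing = tuple(float(s) for s in config.voxel_spacing)
    lo, hi = config.tumor_radius_range

    radii = tuple(float(rng.uniform(lo, hi)) for _ in range(3))
    # center jittered around the grid center but always a voxel index, so the
    # peak of the noiseless profile is attained exactly at one voxel
    center = []
    for n, s, r in zip(shape, spacing, radii):
        mid = n // 2
        slack = max(0, int((n * s / 2 - r - 2 * s) / s))
        jitter = int(rng.integers(-min(3, slack), min(3, slack) + 1)) if slack else 0
        center.append(mid + jitter)
    center = tuple(center)

    suv0 = max(3.0, float(rng.lognormal(*_lognormal_params(*config.baseline_suvmax_dist))))
    dsuv_mean, dsuv_sd = (
        config.responder_dsuv_dist if responder else config.nonresponder_dsuv_dist
    )
    # keep the interim peak visibly above background: peak*(1+d/100) > 1.1*bg
    dsuv_floor = max(-99.0, 100.0 * (1.1 * config.background_suv / suv0 - 1.0))
    dsuv = _truncated_normal(rng, dsuv_mean, dsuv_sd, dsuv_floor, 100.0)
    dmtv_mean, dmtv_sd = (
        config.responder_dmtv_dist if responder else config.nonresponder_dmtv_dist
    )
    dmtv = _truncated_normal(rng, dmtv_mean, dmtv_sd, -99.0, 100.0)
    adc0 = _truncated_normal(rng, *config.baseline_adc_dist, 0.4, 3.0)
    dadc_mean, dadc_sd = (
        config.responder_dadc_dist if responder else config.nonresponder_dadc_dist
    )
    # tumor ADC stays below background so the lesion remains dark on the map
    dadc_ceiling = min(100.0, 100.0 * (0.95 * config.background_adc / adc0 - 1.0))
    dadc = _truncated_normal(rng, dadc_mean, dadc_sd, -80.0, dadc_ceiling)

    interim_radii = tuple(r * (1.0 + dmtv / 100.0) ** (1.0 / 3.0) for r in radii)
    suv1 = suv0 * (1.0 + dsuv / 100.0)
    adc1 = adc0 * (1.0 + dadc / 100.0)

    texture0 = texture1 = None
    if config.texture_flag and responder:
        texture0 = _make_texture(shape, config.texture_amplitude, config.texture_smoothing, rng)
        texture1 = _make_texture(shape, config.texture_amplitude, config.texture_smoothing, rng)

    pet0 = render_tumor_pet(center, radii, suv0, config.background_suv,
                            config.noise_sigma, shape, spacing, rng, texture0)
    pet1 = render_tumor_pet(center, interim_radii, suv1, config.background_suv,
                            config.noise_sigma, shape, spacing, rng, texture1)

    dwi0 = render_dwi_pair(
        _adc_truth_field(shape, spacing, center, radii, adc0, config.background_adc),
        config.s0_level, config.b_high, config.noise_sigma, rng)
    dwi1 = render_dwi_pair(
        _adc_truth_field(shape, spacing, center, interim_radii, adc1, config.background_adc),
        config.s0_level, config.b_high, config.noise_sigma, rng)

    grade = assign_grade(responder, rng)
    prev = config.subtype_prevalence
    flags = {}
    for key in ("ER", "PR", "HER2"):
        p = prev[key]
        rate = p.responder if responder else p.nonresponder
        flags[key] = bool(rng.random() < rate)

    return PatientStudy(
        patient_id=f"P{index:03d}",
        pet_baseline=pet0,
        pet_interim=pet1,
        dwi_baseline=dwi0,
        dwi_interim=dwi1,
        tumor_center=center,
        tumor_radii=radii,
        tumor_radii_interim=interim_radii,
        true_response=responder,
        grade=grade,
        er_positive=flags["ER"],
        pr_positive=flags["PR"],
        her2_positive=flags["HER2"],
        true_suv0=suv0,
        true_dsuv=dsuv,
        true_dmtv=dmtv,
        true_adc0=adc0,
        true_dadc=dadc,
    )


def _adc_truth_field(shape, spacing, center, radii, tumor_adc_e3, background_adc_e3) -> VoxelVolume:
    """Ground-truth ADC field in mm^2/s: uniform tumor in uniform background."""
    rho2 = _ellipsoid_rho2(shape, spacing, center, radii)
    values = np.full(shape, background_adc_e3 * 1e-3)
    values[rho2 <= 1.0] = tumor_adc_e3 * 1e-3
    return VoxelVolume(values, spacing, "ADC")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a lognormal with given mean/sd."""
    var = sd**2
    sigma2 = np.log1p(var / mean**2)
    return float(np.log(mean) - sigma2 / 2), float(np.sqrt(sigma2))


def generate_cohort(config: CohortConfig) -> list[PatientStudy]:
    """Generate the full seeded cohort: responders first, then non-responders.

    Identical configs (including seed) produce bit-identical cohorts.
    """
    config.validate()
    cohort = []
    for i in range(config.n_responders + config.n_nonresponders):
        cohort.append(_generate_patient(i, i < config.n_responders, config))
    return cohort


def write_cohort(cohort: list[PatientStudy], out_dir: str) -> pd.DataFrame:
    """Write all volumes as NIfTI-1 plus a manifest CSV; return the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for study in cohort:
        paths = {}
        for tag, vol in [
            ("pet_baseline", study.pet_baseline),
            ("pet_interim", study.pet_interim),
            ("dwi0_b0", study.dwi_baseline[0]),
            ("dwi0_bhigh", study.dwi_baseline[1]),
            ("dwi1_b0", study.dwi_interim[0]),
            ("dwi1_bhigh", study.dwi_interim[1]),
        ]:
            path = os.path.join(out_dir, f"{study.patient_id}_{tag}.nii.gz")
            vol.save_nifti(path)
            paths[tag] = path
        rows.append({
            "patient_id": study.patient_id,
            "grade": study.grade,
            "true_response": study.true_response,
            "ER": study.er_positive,
            "PR": study.pr_positive,
            "HER2": study.her2_positive,
            **paths,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
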