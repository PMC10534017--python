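"""Synthetic CT phantom cohorts for exercising the prediction pipeline.

Each phantom is a lung-like background (noisy, strongly negative HU) holding a
single ellipsoidal soft-tissue tumor whose mean intensity and internal
heterogeneity can be shifted for event-positive subjects.  The two bundled
presets mirror the composition of the studied clinical cohorts: a surgery-like
cohort of 83 subjects with 7 local failures (tumors 0.6–6 cc) and an SBRT-like
cohort of 84 subjects with 9 local failures (0.9–4.7 cc, with prescription
dose and fraction count).

The planted image–outcome effect (``effect_mean_hu``, ``effect_texture``) is a
property of the test harness, not an estimate of any clinical effect size:
the clinical datasets carry no published quantitative link between image
content and failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume, PatientRecord, records_to_frame, write_volume

__all__ = [
    "CohortConfig",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
    "surgery_preset",
    "sbrt_preset",
]

#: Gaussian-blur FWHM (mm) of the in-tumor texture field.
TEXTURE_FWHM_MM = 3.0
#: Baseline SD (HU) of the in-tumor texture field at heterogeneity 1.
TEXTURE_SD_HU = 30.0
#: Minimum clearance (mm) between tumor surface and grid boundary.
TUMOR_MARGIN_MM = 8.0

# SBRT fractionation schemes in use: 10 Gy x 5, 12/12.5 Gy x 4, 18-20 Gy x 3.
_SBRT_SCHEMES = [(50.0, 5), (48.0, 4), (50.0, 4), (54.0, 3), (60.0, 3)]


@dataclass
class CohortConfig:
    """Generator settings for one phantom cohort."""

    n_subjects: int
    n_events: int
    cohort_kind: str  # "surgery" | "sbrt"
    tumor_volume_range_cc: tuple[float, float] = (0.6, 6.0)
    background_hu: float = -800.0
    tumor_hu_base: float = 20.0
    noise_sd_hu: float = 20.0
    effect_mean_hu: float = 0.0
    effect_texture: float = 1.0
    heterogeneity: float = 1.0
    age_range: tuple[float, float] = (51.0, 88.0)
    cci_range: tuple[int, int] = (0, 8)
    male_fraction: float = 0.5
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_kind not in ("surgery", "sbrt"):
            raise ValueError(f"cohort_kind must be 'surgery' or 'sbrt', got {self.cohort_kind!r}")
        if self.n_events > self.n_subjects:
            raise ValueError(
                f"n_events ({self.n_events}) exceeds n_subjects ({self.n_subjects})"
            )
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        lo, hi = self.tumor_volume_range_cc
        if not (0 < lo <= hi):
            raise ValueError(f"invalid tumor_volume_range_cc {self.tumor_volume_range_cc}")


@dataclass
class PhantomCase:
    """One phantom subject: CT volume, aligned binary mask, clinical record."""

    volume: CTVolume
    mask: np.ndarray
    record: Optional[PatientRecord] = None


def surgery_preset(
    seed: int = 0, effect_mean_hu: float = 0.0, effect_texture: float = 1.0, **overrides
) -> CohortConfig:
    """83-subject / 7-event surgery-like cohort (tumors 0.6–6 cc, no treatment fields)."""
    cfg = CohortConfig(
        n_subjects=83,
        n_events=7,
        cohort_kind="surgery",
        tumor_volume_range_cc=(0.6, 6.0),
        age_range=(51.0, 88.0),
        male_fraction=0.47,
        effect_mean_hu=effect_mean_hu,
        effect_texture=effect_texture,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def sbrt_preset(
    seed: int = 0, effect_mean_hu: float = 0.0, effect_texture: float = 1.0, **overrides
) -> CohortConfig:
    """84-subject / 9-event SBRT-like cohort (0.9–4.7 cc, dose + fractionation)."""
    cfg = CohortConfig(
        n_subjects=84,
        n_events=9,
        cohort_kind="sbrt",
        tumor_volume_range_cc=(0.9, 4.7),
        age_range=(52.0, 100.0),
        male_fraction=0.56,
        effect_mean_hu=effect_mean_hu,
        effect_texture=effect_texture,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _ellipsoid_semiaxes(tumor_volume_cc: float, rng: np.random.Generator) -> np.ndarray:
    """Semi-axes (mm) of a mildly anisotropic ellipsoid of the requested volume."""
    ratios = rng.uniform(0.75, 1.3, size=3)
    # volume of ellipsoid = 4/3 pi a b c; 1 cc = 1000 mm^3
    scale = (tumor_volume_cc * 1000.0 * 3.0 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    return ratios * scale


def generate_phantom(
    shape: tuple[int, int, int] = (128, 128, 128),
    tumor_volume_cc: float = 1.75,
    heterogeneity: float = 1.0,
    mean_shift_hu: float = 0.0,
    seed: int = 0,
    *,
    spacing_mm: float = 1.0,
    background_hu: float = -800.0,
    tumor_hu_base: float = 20.0,
    noise_sd_hu: float = 20.0,
) -> PhantomCase:
    """Generate one phantom volume + mask (no clinical record).

    The tumor is an ellipsoid of the requested volume (within voxelization
    error), placed uniformly at random subject to an 8 mm clearance from every
    grid face.  In-mask voxels take ``tumor_hu_base + mean_shift_hu`` plus a
    smooth Gaussian-blurred texture field scaled by ``heterogeneity``;
    Gaussian image noise of SD ``noise_sd_hu`` is added everywhere.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    semi = _ellipsoid_semiaxes(tumor_volume_cc, rng)  # mm, (z, y, x)

    extent_mm = np.array(shape) * spacing_mm
    lo = semi + TUMOR_MARGIN_MM
    hi = extent_mm - semi - TUMOR_MARGIN_MM
    if np.any(lo > hi):
        raise ValueError(
            f"tumor with semi-axes {np.round(semi, 1)} mm does not fit in a "
            f"{tuple(extent_mm)} mm grid with the required {TUMOR_MARGIN_MM} mm margin"
        )
    center_mm = rng.uniform(lo, hi)

    coords = [np.arange(n) * spacing_mm + spacing_mm / 2.0 for n in shape]
    zz = ((coords[0] - center_mm[0]) / semi[0]) ** 2
    yy = ((coords[1] - center_mm[1]) / semi[1]) ** 2
    xx = ((coords[2] - center_mm[2]) / semi[2]) ** 2
    mask = (
        zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    ) <= 1.0
    mask = mask.astype(np.uint8)

    voxels = np.full(shape, background_hu, dtype=np.float32)
    tumor_hu = tumor_hu_base + mean_shift_hu
    voxels[mask > 0] = tumor_hu

    if heterogeneity > 0:
        sigma_vox = TEXTURE_FWHM_MM / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spacing_mm
        texture = ndimage.gaussian_filter(
            rng.standard_normal(shape).astype(np.float32), sigma=sigma_vox
        )
        sd = float(texture.std())
        if sd > 0:
            texture *= TEXTURE_SD_HU * heterogeneity / sd
        voxels[mask > 0] += texture[mask > 0]

    if noise_sd_hu > 0:
        voxels += rng.normal(0.0, noise_sd_hu, size=shape).astype(np.float32)

    volume = CTVolume(voxels=voxels, spacing=(spacing_mm,) * 3)
    return PhantomCase(volume=volume, mask=mask)


def generate_cohort(config: CohortConfig) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Generate a full phantom cohort plus its manifest.

    Exactly ``n_events`` randomly chosen subjects are labelled positive and
    receive the planted intensity shift and heterogeneity multiplier.
    Demographics are sampled uniformly within the configured ranges and carry
    no label association.  Tumor volumes are log-uniform over the configured
    range (right-skewed, as clinical tumor-size distributions are).
    """
    rng = np.random.default_rng(config.seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=config.n_subjects)
    event_idx = set(
        rng.choice(config.n_subjects, size=config.n_events, replace=False).tolist()
    )
    lo, hi = config.tumor_volume_range_cc
    volumes_cc = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_subjects))
    genders = (rng.uniform(size=config.n_subjects) < config.male_fraction).astype(int)
    ages = rng.uniform(*config.age_range, size=config.n_subjects)
    ccis = rng.integers(config.cci_range[0], config.cci_range[1] + 1, size=config.n_subjects)
    scheme_idx = rng.integers(0, len(_SBRT_SCHEMES), size=config.n_subjects)

    cases: list[PhantomCase] = []
    width = len(str(config.n_subjects))
    for i in range(config.n_subjects):
        label = int(i in event_idx)
        shift = config.effect_mean_hu if label else 0.0
        het = config.heterogeneity * (config.effect_texture if label else 1.0)
        case = generate_phantom(
            shape=config.grid_shape,
            tumor_volume_cc=float(volumes_cc[i]),
            heterogeneity=het,
            mean_shift_hu=shift,
            seed=int(case_seeds[i]),
            spacing_mm=config.spacing_mm,
            background_hu=config.background_hu,
            tumor_hu_base=config.tumor_hu_base,
            noise_sd_hu=config.noise_sd_hu,
        )
        voxel_cc = float(case.mask.sum()) * case.volume.voxel_volume_mm3 / 1000.0
        dose, nfx = (None, None)
        if config.cohort_kind == "sbrt":
            dose, nfx = _SBRT_SCHEMES[scheme_idx[i]]
        case.record = PatientRecord(
            id=f"{config.cohort_kind}_{i:0{width}d}",
            cohort=config.cohort_kind,
            gender=int(genders[i]),
            age=float(np.round(ages[i], 1)),
            tumor_volume_cc=float(np.round(voxel_cc, 3)),
            cci=int(ccis[i]),
            label=label,
            dose_gy=dose,
            n_fractions=nfx,
        )
        cases.append(case)

    manifest = records_to_frame([c.record for c in cases])
    return cases, manifest


def write_cohort(
    cases: Sequence[PhantomCase], out_dir: str | Path, fmt: str = "nii.gz"
) -> Path:
    """Write one volume + one mask per case, plus the manifest CSV.

    Returns the manifest path.  ``fmt`` is ``nii.gz``, ``nii`` or ``nrrd``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        if case.record is None:
            raise ValueError("cannot write a cohort of record-less cases")
        write_volume(case.volume, out_dir / f"{case.record.id}_ct.{fmt}")
        mask_vol = CTVolume(
            voxels=case.mask.astype(np.uint8),
            spacing=case.volume.spacing,
            origin=case.volume.origin,
        )
        write_volume(mask_vol, out_dir / f"{case.record.id}_mask.{fmt}")
    manifest = records_to_frame([c.record for c in cases])
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
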