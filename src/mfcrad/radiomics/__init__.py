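"""Handcrafted 3D radiomics: 105 features from a GTV-masked CT volume.

Families and sizes: 13 shape, 18 intensity, 20 histogram, 22 GLCM, 16 GLRLM
and 16 GLSZM.  Shape and intensity features come from the original volume;
histogram and texture families use a fixed-bin-number discretization
(32 bins by default).  GLCM/GLRLM features are averaged over the 13 unique
directions of the 26-neighbourhood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .discretize import DiscretizedROI, discretize_fbn
from .firstorder import (
    HISTOGRAM_FEATURES,
    INTENSITY_FEATURES,
    histogram_features,
    intensity_features,
)
from .matrices import DIRECTIONS_13, TextureMatrix, compute_glcm, compute_glrlm, compute_glszm
from .shape import SHAPE_FEATURES, shape_features
from .texture import (
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    average_feature_dicts,
    texture_features,
)

__all__ = [
    "RadiomicsConfig",
    "extract_handcrafted",
    "feature_names",
    "DiscretizedROI",
    "discretize_fbn",
    "TextureMatrix",
    "DIRECTIONS_13",
    "compute_glcm",
    "compute_glrlm",
    "compute_glszm",
    "texture_features",
    "intensity_features",
    "histogram_features",
    "shape_features",
    "FAMILY_SIZES",
]

FAMILY_SIZES = {
    "shape": 13,
    "intensity": 18,
    "histogram": 20,
    "glcm": 22,
    "glrlm": 16,
    "glszm": 16,
}


@dataclass
class RadiomicsConfig:
    """Extraction settings; defaults match the reference pipeline."""

    n_bins: int = 32
    glcm_distance: int = 1
    surface_mode: str = "faces"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def feature_names(config: RadiomicsConfig | None = None) -> list[str]:
    """The 105 feature names in stable extraction order (``family__name``)."""
    names = []
    names += [f"shape__{n}" for n in SHAPE_FEATURES]
    names += [f"intensity__{n}" for n in INTENSITY_FEATURES]
    names += [f"histogram__{n}" for n in HISTOGRAM_FEATURES]
    names += [f"glcm__{n}" for n in GLCM_FEATURES]
    names += [f"glrlm__{n}" for n in GLRLM_FEATURES]
    names += [f"glszm__{n}" for n in GLSZM_FEATURES]
    return names


def extract_handcrafted(
    volume, mask: np.ndarray, config: RadiomicsConfig | None = None
) -> dict[str, float]:
    """Extract all 105 handcrafted features from an aligned volume/mask pair.

    ``volume`` may be a :class:`~mfcrad.volume.CTVolume` or a raw 3D array
    (then 1 mm spacing is assumed).  Returns an ordered name -> value dict;
    all values are finite for ROIs with at least 2 voxels and 2 distinct
    intensities.  Single-voxel ROIs yield zero texture features and a warning.
    """
    config = config or RadiomicsConfig()
    if hasattr(volume, "voxels"):
        voxels = volume.voxels
        spacing = volume.spacing
    else:
        voxels = np.asarray(volume)
        spacing = (1.0, 1.0, 1.0)
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    if mask.shape != voxels.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {voxels.shape}")

    out: dict[str, float] = {}
    for k, v in shape_features(mask, spacing, surface_mode=config.surface_mode).items():
        out[f"shape__{k}"] = v
    for k, v in intensity_features(voxels, mask).items():
        out[f"intensity__{k}"] = v

    droi = discretize_fbn(voxels, mask, config.n_bins)
    for k, v in histogram_features(droi).items():
        out[f"histogram__{k}"] = v

    if droi.n_voxels < 2:
        warnings.warn("single-voxel ROI: texture features set to 0", stacklevel=2)
        for fam, names in (("glcm", GLCM_FEATURES), ("glrlm", GLRLM_FEATURES), ("glszm", GLSZM_FEATURES)):
            for n in names:
                out[f"{fam}__{n}"] = 0.0
        return out

    per_dir, _ = compute_glcm(droi, distance=config.glcm_distance)
    glcm_avg = average_feature_dicts([texture_features(m) for m in per_dir])
    for k, v in glcm_avg.items():
        out[f"glcm__{k}"] = v

    glrlm_avg = average_feature_dicts([texture_features(m) for m in compute_glrlm(droi)])
    for k, v in glrlm_avg.items():
        out[f"glrlm__{k}"] = v

    for k, v in texture_features(compute_glszm(droi)).items():
        out[f"glszm__{k}"] = v

    assert list(out.keys()) == feature_names(config)
    return out
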