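"""End-to-end dataset assembly: images -> feature blocks -> fused table.

`CohortDataset` is the in-memory object the validation harness consumes: a
fused, block-tagged feature table aligned with binary outcome labels.  It can
be built from in-memory phantom cases or from a directory of volumes/masks
plus a manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .encoder import EncoderConfig, UNetEncoder, crop_voi, normalize_input
from .fusion import FeatureTable, assemble_feature_blocks
from .radiomics import RadiomicsConfig, extract_handcrafted
from .synthetic import PhantomCase
from .volume import CTVolume, PatientRecord, load_manifest, read_volume, resample_isotropic

logger = logging.getLogger(__name__)

__all__ = [
    "CohortDataset",
    "extract_handcrafted_block",
    "extract_deep_block",
    "clinical_block",
    "build_dataset",
    "load_cases",
]


@dataclass
class CohortDataset:
    """Fused feature table + labels for one cohort."""

    table: FeatureTable
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.loc[self.table.df.index]

    @property
    def ids(self) -> list:
        return list(self.table.df.index)


def extract_handcrafted_block(
    cases: Sequence[PhantomCase], config: RadiomicsConfig | None = None
) -> pd.DataFrame:
    """105 handcrafted features per case, indexed by patient id."""
    config = config or RadiomicsConfig()
    rows = {}
    for case in cases:
        rows[case.record.id] = extract_handcrafted(case.volume, case.mask, config)
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df


def extract_deep_block(
    cases: Sequence[PhantomCase],
    encoder: UNetEncoder | None = None,
    config: EncoderConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """512 deep features per case from the frozen encoder."""
    config = config or EncoderConfig()
    encoder = encoder or UNetEncoder(config=config, seed=seed)
    rows = {}
    for case in cases:
        block = normalize_input(
            crop_voi(case.volume, case.mask, voi_mm=config.voi_mm), config.hu_window
        )
        rows[case.record.id] = encoder.encode(block)
        logger.debug("encoded %s", case.record.id)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"deep_{i:03d}" for i in range(df.shape[1])]
    return df


def clinical_block(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Demographic (+ treatment for SBRT) covariates per patient."""
    rows = {r.id: r.clinical_features() for r in records}
    return pd.DataFrame.from_dict(rows, orient="index")


def build_dataset(
    cases: Sequence[PhantomCase],
    radiomics_config: RadiomicsConfig | None = None,
    encoder_config: EncoderConfig | None = None,
    encoder: UNetEncoder | None = None,
    encoder_seed: int = 0,
) -> CohortDataset:
    """Full pipeline over in-memory cases: all three blocks, fused."""
    records = [c.record for c in cases]
    if any(r is None for r in records):
        raise ValueError("all cases must carry a PatientRecord")
    hand = extract_handcrafted_block(cases, radiomics_config)
    deep = extract_deep_block(cases, encoder=encoder, config=encoder_config, seed=encoder_seed)
    clin = clinical_block(records)
    table = assemble_feature_blocks(hand, deep, clin)
    labels = pd.Series({r.id: r.label for r in records}, name="label")
    return CohortDataset(table=table, labels=labels)


def load_cases(
    manifest_path: str | Path,
    volumes_dir: str | Path | None = None,
    target_mm: float = 1.0,
    fmt: str = "nii.gz",
) -> list[PhantomCase]:
    """Load a written cohort (volume + mask per manifest row), resampled to
    the isotropic analysis grid."""
    manifest_path = Path(manifest_path)
    volumes_dir = Path(volumes_dir) if volumes_dir else manifest_path.parent
    records = load_manifest(manifest_path)
    cases = []
    for r in records:
        vol = read_volume(volumes_dir / f"{r.id}_ct.{fmt}")
        mask_vol = read_volume(volumes_dir / f"{r.id}_mask.{fmt}")
        vol, mask = resample_isotropic(vol, mask_vol.voxels, target_mm)
        cases.append(PhantomCase(volume=vol, mask=mask, record=r))
    return cases
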