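"""CT volume and mask I/O, isotropic resampling, and cohort manifests.

Conventions
-----------
Voxel arrays are indexed ``(z, y, x)`` with 0-based indices; ``spacing`` and
``origin`` follow the same axis order, in millimetres.  Hounsfield units are
assumed calibrated by the file reader.  Masks must live on exactly the same
grid as their volume — no registration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "CTVolume",
    "PatientRecord",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "load_manifest",
    "records_to_frame",
]

MANIFEST_COLUMNS = [
    "id",
    "cohort",
    "gender",
    "age",
    "tumor_volume_cc",
    "cci",
    "dose_gy",
    "n_fractions",
    "label",
]


@dataclass
class CTVolume:
    """A 3D CT grid in Hounsfield units with geometry metadata.

    ``voxels`` is ``(z, y, x)``; ``spacing``/``origin`` are mm in the same
    axis order.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"CTVolume requires a 3D array, got {self.voxels.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class PatientRecord:
    """Per-patient covariates and the binary local-failure label."""

    id: str
    cohort: str  # "surgery" | "sbrt"
    gender: int
    age: float
    tumor_volume_cc: float
    cci: int
    label: int
    dose_gy: Optional[float] = None
    n_fractions: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cohort not in ("surgery", "sbrt"):
            raise ValueError(f"cohort must be 'surgery' or 'sbrt', got {self.cohort!r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.gender not in (0, 1):
            raise ValueError(f"gender must be 0 or 1, got {self.gender!r}")
        if self.cohort == "sbrt":
            if self.dose_gy is None:
                raise ValueError(f"sbrt record {self.id!r} missing dose_gy")
            if self.n_fractions is None:
                raise ValueError(f"sbrt record {self.id!r} missing n_fractions")

    def clinical_features(self) -> dict[str, float]:
        """Demographic (and, for SBRT, treatment) covariates as a flat dict."""
        feats = {
            "gender": float(self.gender),
            "age": float(self.age),
            "tumor_volume_cc": float(self.tumor_volume_cc),
            "cci": float(self.cci),
        }
        if self.cohort == "sbrt":
            feats["dose_gy"] = float(self.dose_gy)
            feats["n_fractions"] = float(self.n_fractions)
        return feats


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".nrrd") or name.endswith(".nhdr"):
        return "nrrd"
    raise ValueError(f"unknown volume format for {path} (expected NIfTI or NRRD)")


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI or NRRD volume; format is auto-detected by extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _detect_format(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
        zooms = img.header.get_zooms()[:3]
        # nibabel arrays are (x, y, z); transpose to (z, y, x)
        voxels = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
        return CTVolume(voxels=voxels, spacing=spacing, origin=origin)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.GetDimension()}D")
    voxels = sitk.GetArrayFromImage(img)  # already (z, y, x)
    spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
    origin = tuple(float(o) for o in img.GetOrigin()[::-1])
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin)


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI or NRRD depending on the file extension."""
    path = Path(path)
    fmt = _detect_format(path)
    try:
        if fmt == "nifti":
            data = np.transpose(volume.voxels, (2, 1, 0))
            affine = np.diag(list(volume.spacing[::-1]) + [1.0])
            affine[:3, 3] = volume.origin[::-1]
            nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
        else:
            img = sitk.GetImageFromArray(volume.voxels)
            img.SetSpacing(tuple(volume.spacing[::-1]))
            img.SetOrigin(tuple(volume.origin[::-1]))
            sitk.WriteImage(img, str(path), useCompression=True)
    except (OSError, RuntimeError) as exc:
        raise OSError(f"failed to write volume to {path}: {exc}") from exc
    return path


def _to_sitk(voxels: np.ndarray, spacing: Sequence[float], origin: Sequence[float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(voxels))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    img.SetOrigin(tuple(float(o) for o in origin[::-1]))
    return img


def resample_isotropic(
    volume: CTVolume,
    mask: np.ndarray,
    target_mm: float = 1.0,
) -> tuple[CTVolume, np.ndarray]:
    """Resample a volume/mask pair to an isotropic grid.

    The volume is interpolated trilinearly; the mask by nearest neighbour and
    re-binarized.  Physical extent is preserved to within one voxel.  Inputs
    already on the target grid are returned unchanged.
    """
    mask = np.asarray(mask)
    if mask.shape != volume.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    if not np.any(mask):
        raise ValueError("mask is empty")
    if all(abs(s - target_mm) < 1e-9 for s in volume.spacing):
        return volume, (mask > 0).astype(np.uint8)

    src = _to_sitk(volume.voxels.astype(np.float32), volume.spacing, volume.origin)
    msk = _to_sitk((mask > 0).astype(np.uint8), volume.spacing, volume.origin)

    new_size = [
        max(1, int(round(n * s / target_mm)))
        for n, s in zip(src.GetSize(), src.GetSpacing())
    ]
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing((target_mm,) * 3)
    res.SetOutputOrigin(src.GetOrigin())
    res.SetOutputDirection(src.GetDirection())
    res.SetSize(new_size)

    res.SetInterpolator(sitk.sitkLinear)
    res.SetDefaultPixelValue(float(np.min(volume.voxels)))
    vol_out = sitk.GetArrayFromImage(res.Execute(src))

    res.SetInterpolator(sitk.sitkNearestNeighbor)
    res.SetDefaultPixelValue(0)
    mask_out = (sitk.GetArrayFromImage(res.Execute(msk)) > 0.5).astype(np.uint8)
    if not np.any(mask_out):
        raise ValueError("mask is empty after resampling")

    out = CTVolume(
        voxels=vol_out,
        spacing=(target_mm,) * 3,
        origin=volume.origin,
    )
    return out, mask_out


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Manifest DataFrame (one row per record, canonical column order)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "cohort": r.cohort,
                "gender": r.gender,
                "age": r.age,
                "tumor_volume_cc": r.tumor_volume_cc,
                "cci": r.cci,
                "dose_gy": r.dose_gy if r.dose_gy is not None else "",
                "n_fractions": r.n_fractions if r.n_fractions is not None else "",
                "label": r.label,
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def load_manifest(path: str | Path) -> list[PatientRecord]:
    """Load and validate a cohort manifest CSV into typed records.

    Required columns: id, gender, age, tumor_volume_cc, cci, label (plus
    dose_gy / n_fractions, which may be empty only for surgery rows).  The
    cohort column is optional; absent, a row is tagged sbrt iff it carries
    treatment fields.
    """
    df = pd.read_csv(path)
    required = ["id", "gender", "age", "tumor_volume_cc", "cci", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing required column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        label = row["label"]
        if label not in (0, 1):
            raise ValueError(f"manifest {path}: row id={row['id']!r} has label={label!r} outside {{0,1}}")
        def _opt(col):
            if col not in df.columns:
                return None
            v = row[col]
            if pd.isna(v) or v == "":
                return None
            return float(v)

        dose = _opt("dose_gy")
        nfx = _opt("n_fractions")
        cohort = row.get("cohort")
        if not isinstance(cohort, str) or cohort == "":
            cohort = "sbrt" if dose is not None else "surgery"
        if cohort == "sbrt":
            if dose is None:
                raise ValueError(
                    f"manifest {path}: sbrt row id={row['id']!r} missing dose_gy"
                )
            if nfx is None:
                raise ValueError(
                    f"manifest {path}: sbrt row id={row['id']!r} missing n_fractions"
                )
        records.append(
            PatientRecord(
                id=str(row["id"]),
                cohort=cohort,
                gender=int(row["gender"]),
                age=float(row["age"]),
                tumor_volume_cc=float(row["tumor_volume_cc"]),
                cci=int(row["cci"]),
                label=int(label),
                dose_gy=dose,
                n_fractions=int(nfx) if nfx is not None else None,
            )
        )
    return records
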