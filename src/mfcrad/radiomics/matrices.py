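"""Gray-level texture matrices: GLCM, GLRLM and GLSZM.

GLCM and GLRLM are computed along the 13 unique (non-opposite) directions of
the 3D 26-neighbourhood at voxel distance 1; GLSZM uses 26-connected zones
and has no directional structure.  All counting is restricted to in-mask
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = ["TextureMatrix", "DIRECTIONS_13", "compute_glcm", "compute_glrlm", "compute_glszm"]


def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dz, dy, dx)
                if d == (0, 0, 0):
                    continue
                # keep one of each opposite pair: first nonzero component > 0
                for c in d:
                    if c != 0:
                        if c > 0:
                            dirs.append(d)
                        break
    return tuple(dirs)


#: The 13 unique non-opposite unit offsets of the 26-neighbourhood.
DIRECTIONS_13 = _unique_directions()
assert len(DIRECTIONS_13) == 13


@dataclass
class TextureMatrix:
    """A texture count matrix with its provenance.

    ``counts`` rows index gray level (1..n_bins); columns index the second
    dimension (gray level for GLCM, run length for GLRLM, zone size for
    GLSZM), 1-based in value, 0-based in storage.
    """

    kind: str  # "glcm" | "glrlm" | "glszm"
    counts: np.ndarray
    direction: Optional[tuple[int, int, int]] = None  # None = aggregated / directionless
    n_bins: int = 0
    n_voxels: int = 0

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return self.counts.astype(np.float64) / total


def _shift_pairs(droi: DiscretizedROI, direction: tuple[int, int, int]):
    """In-mask voxel/neighbour bin pairs for one offset (vectorised slicing)."""
    bins, mask = droi.bins, droi.mask
    shape = bins.shape
    src = []
    dst = []
    for n, d in zip(shape, direction):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    a = bins[tuple(src)]
    b = bins[tuple(dst)]
    valid = (mask[tuple(src)] > 0) & (mask[tuple(dst)] > 0)
    return a[valid], b[valid]


def compute_glcm(
    droi: DiscretizedROI, distance: int = 1, symmetric: bool = True
) -> tuple[list[TextureMatrix], TextureMatrix]:
    """Symmetric co-occurrence counts for each of the 13 directions.

    Returns (per-direction matrices, aggregated matrix), where the aggregate
    is the element-wise mean of the 13 directional matrices.
    """
    n = droi.n_bins
    per_dir: list[TextureMatrix] = []
    any_pairs = False
    for d in DIRECTIONS_13:
        off = tuple(distance * c for c in d)
        a, b = _shift_pairs(droi, off)
        m = np.zeros((n, n), dtype=np.float64)
        if a.size:
            any_pairs = True
            np.add.at(m, (a - 1, b - 1), 1.0)
            if symmetric:
                m = m + m.T
        per_dir.append(
            TextureMatrix(kind="glcm", counts=m, direction=d, n_bins=n, n_voxels=droi.n_voxels)
        )
    if not any_pairs:
        raise ValueError("ROI has no valid voxel pair in any direction")
    agg = np.mean([m.counts for m in per_dir], axis=0)
    aggregated = TextureMatrix(
        kind="glcm", counts=agg, direction=None, n_bins=n, n_voxels=droi.n_voxels
    )
    return per_dir, aggregated


def _runs_along(droi: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts R[g, l] along one direction (rows 1..n_bins, cols 1..max)."""
    bins, mask = droi.bins, droi.mask
    shape = bins.shape
    n = droi.n_bins
    # a run takes at most max(shape) steps along any direction
    counts = np.zeros((n, max(shape)), dtype=np.float64)

    # a voxel starts a run if its backwards neighbour is absent or different
    prev = tuple(-c for c in direction)
    in_mask = mask > 0
    same_prev = np.zeros(shape, dtype=bool)
    src, dst = [], []
    for nn, d in zip(shape, prev):
        if d >= 0:
            src.append(slice(0, nn - d))
            dst.append(slice(d, nn))
        else:
            src.append(slice(-d, nn))
            dst.append(slice(0, nn + d))
    # src voxels pair with their previous neighbour at src + prev (= dst)
    sp = (
        in_mask[tuple(src)]
        & in_mask[tuple(dst)]
        & (bins[tuple(src)] == bins[tuple(dst)])
    )
    same_prev[tuple(src)] = sp
    starts = np.argwhere(in_mask & ~same_prev)

    dz, dy, dx = direction
    nz, ny, nx = shape
    for z, y, x in starts:
        g = bins[z, y, x]
        length = 1
        zz, yy, xx = z + dz, y + dy, x + dx
        while 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and mask[zz, yy, xx] and bins[zz, yy, xx] == g:
            length += 1
            zz += dz
            yy += dy
            xx += dx
        counts[g - 1, length - 1] += 1.0

    # trim trailing all-zero run-length columns (keep at least one column)
    used = np.nonzero(counts.sum(axis=0))[0]
    last = used[-1] + 1 if used.size else 1
    return counts[:, :last]


def compute_glrlm(droi: DiscretizedROI) -> list[TextureMatrix]:
    """Run-length matrices for each of the 13 directions."""
    if droi.n_voxels == 0:
        raise ValueError("empty ROI")
    out = []
    for d in DIRECTIONS_13:
        counts = _runs_along(droi, d)
        out.append(
            TextureMatrix(kind="glrlm", counts=counts, direction=d, n_bins=droi.n_bins, n_voxels=droi.n_voxels)
        )
    return out


_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def compute_glszm(droi: DiscretizedROI) -> TextureMatrix:
    """Zone-size matrix under 26-connectivity (single, directionless matrix)."""
    if droi.n_voxels == 0:
        raise ValueError("empty ROI")
    n = droi.n_bins
    max_size = droi.n_voxels
    counts = np.zeros((n, max_size), dtype=np.float64)
    present = np.unique(droi.in_mask_bins)
    for g in present:
        lab, n_zones = ndimage.label(droi.bins == g, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            counts[g - 1, s - 1] += 1.0
    used = np.nonzero(counts.sum(axis=0))[0]
    last = used[-1] + 1 if used.size else 1
    return TextureMatrix(
        kind="glszm", counts=counts[:, :last], direction=None, n_bins=n, n_voxels=droi.n_voxels
    )
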