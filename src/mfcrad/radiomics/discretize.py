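"""Fixed-bin-number intensity discretization of a masked ROI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedROI", "discretize_fbn"]


@dataclass
class DiscretizedROI:
    """Bin indices 1..n_bins on the volume grid; 0 marks out-of-mask voxels."""

    bins: np.ndarray  # int array, 0 outside mask
    mask: np.ndarray  # uint8
    n_bins: int

    @property
    def in_mask_bins(self) -> np.ndarray:
        return self.bins[self.mask > 0]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


def discretize_fbn(
    volume_voxels: np.ndarray, mask: np.ndarray, n_bins: int = 32
) -> DiscretizedROI:
    """Map in-mask intensities onto ``n_bins`` equal-width bins.

    bin(x) = floor(n_bins * (x - min) / (max - min)) + 1, with x = max mapped
    to n_bins.  A constant ROI maps every voxel to bin 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    if not np.any(mask):
        raise ValueError("mask is empty")
    values = np.asarray(volume_voxels, dtype=np.float64)
    inmask = values[mask > 0]
    lo, hi = float(inmask.min()), float(inmask.max())
    bins = np.zeros(values.shape, dtype=np.int32)
    if hi == lo:
        bins[mask > 0] = 1
    else:
        b = np.floor(n_bins * (values - lo) / (hi - lo)).astype(np.int32) + 1
        np.clip(b, 1, n_bins, out=b)
        bins[mask > 0] = b[mask > 0]
    return DiscretizedROI(bins=bins, mask=mask, n_bins=n_bins)
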