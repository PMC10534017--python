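"""First-order features: 18 intensity-based (raw HU) and 20 histogram-based
(on the fixed-bin-number discretized ROI).

Degenerate ROIs (constant intensity, single voxel) return convention values:
moments that divide by a zero variance are 0, entropy of a single occupied
bin is 0.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI

__all__ = ["INTENSITY_FEATURES", "HISTOGRAM_FEATURES", "intensity_features", "histogram_features"]

INTENSITY_FEATURES = [
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "percentile_10",
    "percentile_90",
    "maximum",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "median_absolute_deviation",
    "coefficient_of_variation",
    "quartile_coefficient_of_dispersion",
    "energy",
    "root_mean_square",
]

HISTOGRAM_FEATURES = [
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "percentile_10",
    "percentile_90",
    "maximum",
    "mode",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "median_absolute_deviation",
    "coefficient_of_variation",
    "quartile_coefficient_of_dispersion",
    "entropy",
    "uniformity",
    "maximum_gradient",
]


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    mu = float(x.mean())
    var = float(x.var())  # population variance
    if var > 0:
        sd = np.sqrt(var)
        skew = float(((x - mu) ** 3).mean() / sd**3)
        kurt = float(((x - mu) ** 4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0
    return mu, var, skew, kurt


def _dispersion(x: np.ndarray) -> dict[str, float]:
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mu = float(x.mean())
    robust = x[(x >= p10) & (x <= p90)]
    out = {
        "median": float(p50),
        "minimum": float(x.min()),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "maximum": float(x.max()),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(x - mu).mean()),
        "robust_mean_absolute_deviation": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
        ),
        "median_absolute_deviation": float(np.abs(x - p50).mean()),
        "coefficient_of_variation": float(x.std() / mu) if mu != 0 else 0.0,
        "quartile_coefficient_of_dispersion": (
            float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0
        ),
    }
    return out


def intensity_features(volume_voxels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """The 18 intensity statistics on raw in-mask HU values."""
    x = np.asarray(volume_voxels, dtype=np.float64)[np.asarray(mask) > 0]
    if x.size == 0:
        raise ValueError("mask is empty")
    mu, var, skew, kurt = _moments(x)
    out = {"mean": mu, "variance": var, "skewness": skew, "kurtosis": kurt}
    out.update(_dispersion(x))
    out["energy"] = float((x**2).sum())
    out["root_mean_square"] = float(np.sqrt((x**2).mean()))
    return {k: out[k] for k in INTENSITY_FEATURES}


def histogram_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 20 histogram statistics on the discretized (1..n_bins) ROI."""
    x = droi.in_mask_bins.astype(np.float64)
    if x.size == 0:
        raise ValueError("mask is empty")
    counts = np.bincount(droi.in_mask_bins.astype(int), minlength=droi.n_bins + 1)[1:]
    p = counts / counts.sum()
    mu, var, skew, kurt = _moments(x)
    out = {"mean": mu, "variance": var, "skewness": skew, "kurtosis": kurt}
    out.update(_dispersion(x))
    out["mode"] = float(np.argmax(counts) + 1)  # smallest bin on ties
    nzp = p[p > 0]
    out["entropy"] = float(-(nzp * np.log2(nzp)).sum())
    out["uniformity"] = float((p**2).sum())
    grad = np.gradient(counts.astype(np.float64)) if counts.size > 1 else np.zeros(1)
    out["maximum_gradient"] = float(np.max(grad))
    return {k: out[k] for k in HISTOGRAM_FEATURES}
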