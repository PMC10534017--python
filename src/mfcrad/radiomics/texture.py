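"""Texture features from GLCM / GLRLM / GLSZM matrices.

Feature definitions follow the Image Biomarker Standardisation Initiative
(IBSI) reference formulations.  Degenerate matrices (zero marginal variance,
single-entry matrices) yield the documented convention values so every
feature remains finite:

* GLCM correlation with zero gray-level variance -> 0
* any ratio with a zero denominator -> 0
* log terms use the 0·log(0) = 0 convention

GLCM and GLRLM features are computed per directional matrix and averaged
over the 13 directions by the caller (IBSI "averaging" aggregation).
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrix

__all__ = [
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "texture_features",
    "average_feature_dicts",
]

GLCM_FEATURES = [
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_norm",
    "inverse_difference_moment",
    "inverse_difference_moment_norm",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
]

GLRLM_FEATURES = [
    "short_run_emphasis",
    "long_run_emphasis",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_norm",
    "run_length_nonuniformity",
    "run_length_nonuniformity_norm",
    "run_percentage",
    "gray_level_variance",
    "run_length_variance",
    "run_entropy",
]

GLSZM_FEATURES = [
    "small_zone_emphasis",
    "large_zone_emphasis",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_zone_low_gray_level_emphasis",
    "small_zone_high_gray_level_emphasis",
    "large_zone_low_gray_level_emphasis",
    "large_zone_high_gray_level_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_norm",
    "zone_size_nonuniformity",
    "zone_size_nonuniformity_norm",
    "zone_percentage",
    "gray_level_variance",
    "zone_size_variance",
    "zone_size_entropy",
]


def _safe_div(a: float, b: float) -> float:
    return float(a / b) if b != 0 else 0.0


def _plogp(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0


def _glcm_features(m: TextureMatrix) -> dict[str, float]:
    p = m.normalized()
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    mu = float((ii * p).sum())  # == joint average for symmetric p
    var = float((((ii - mu) ** 2) * p).sum())

    diff = np.abs(ii - jj)
    ssum = ii + jj

    # p_{x+y}(k), k = 2..2n ; p_{x-y}(k), k = 0..n-1
    pxy_sum = np.zeros(2 * n + 1)
    np.add.at(pxy_sum, ssum.astype(int).ravel(), p.ravel())
    pxy_diff = np.zeros(n)
    np.add.at(pxy_diff, diff.astype(int).ravel(), p.ravel())
    ks = np.arange(2 * n + 1, dtype=np.float64)
    kd = np.arange(n, dtype=np.float64)

    sum_avg = float((ks * pxy_sum).sum())
    diff_avg = float((kd * pxy_diff).sum())

    out: dict[str, float] = {}
    out["joint_average"] = mu
    out["joint_variance"] = var
    out["joint_entropy"] = _plogp(p.ravel())
    out["angular_second_moment"] = float((p**2).sum())
    out["contrast"] = float((diff**2 * p).sum())
    out["dissimilarity"] = float((diff * p).sum())
    out["inverse_difference"] = float((p / (1.0 + diff)).sum())
    out["inverse_difference_norm"] = float((p / (1.0 + diff / n)).sum())
    out["inverse_difference_moment"] = float((p / (1.0 + diff**2)).sum())
    out["inverse_difference_moment_norm"] = float((p / (1.0 + diff**2 / n**2)).sum())
    nz = diff > 0
    out["inverse_variance"] = float((p[nz] / diff[nz] ** 2).sum()) if nz.any() else 0.0
    if var > 0:
        out["correlation"] = float((((ii - mu) * (jj - mu) * p).sum()) / var)
    else:
        out["correlation"] = 0.0
    out["autocorrelation"] = float((ii * jj * p).sum())
    out["cluster_tendency"] = float((((ii + jj - 2 * mu) ** 2) * p).sum())
    out["cluster_shade"] = float((((ii + jj - 2 * mu) ** 3) * p).sum())
    out["cluster_prominence"] = float((((ii + jj - 2 * mu) ** 4) * p).sum())
    out["sum_average"] = sum_avg
    out["sum_variance"] = float((((ks - sum_avg) ** 2) * pxy_sum).sum())
    out["sum_entropy"] = _plogp(pxy_sum)
    out["difference_average"] = diff_avg
    out["difference_variance"] = float((((kd - diff_avg) ** 2) * pxy_diff).sum())
    out["difference_entropy"] = _plogp(pxy_diff)
    return out


def _run_or_zone_features(m: TextureMatrix, names: list[str], total_voxels: int) -> dict[str, float]:
    """Shared GLRLM/GLSZM formulas; column index = run length or zone size."""
    c = m.counts.astype(np.float64)
    ns = c.sum()
    g = np.arange(1, c.shape[0] + 1, dtype=np.float64)  # gray level
    l = np.arange(1, c.shape[1] + 1, dtype=np.float64)  # run length / zone size
    gg, ll = np.meshgrid(g, l, indexing="ij")

    if ns == 0:
        return {k: 0.0 for k in names}

    p = c / ns
    row = c.sum(axis=1)  # per gray level
    col = c.sum(axis=0)  # per length/size

    mu_g = float((gg * p).sum())
    mu_l = float((ll * p).sum())

    vals = [
        float((c / ll**2).sum() / ns),                      # short emphasis
        float((c * ll**2).sum() / ns),                      # long emphasis
        float((c / gg**2).sum() / ns),                      # low gray level
        float((c * gg**2).sum() / ns),                      # high gray level
        float((c / (gg**2 * ll**2)).sum() / ns),            # short + low
        float((c * gg**2 / ll**2).sum() / ns),              # short + high
        float((c * ll**2 / gg**2).sum() / ns),              # long + low
        float((c * gg**2 * ll**2).sum() / ns),              # long + high
        float((row**2).sum() / ns),                         # gray-level nonuniformity
        float((row**2).sum() / ns**2),                      # ... normalised
        float((col**2).sum() / ns),                         # length/size nonuniformity
        float((col**2).sum() / ns**2),                      # ... normalised
        _safe_div(ns, total_voxels),                        # run/zone percentage
        float((((gg - mu_g) ** 2) * p).sum()),              # gray-level variance
        float((((ll - mu_l) ** 2) * p).sum()),              # length/size variance
        _plogp(p.ravel()),                                  # entropy
    ]
    return dict(zip(names, vals))


def texture_features(matrix: TextureMatrix, kind: str | None = None) -> dict[str, float]:
    """Named feature values for one texture matrix."""
    kind = kind or matrix.kind
    if kind == "glcm":
        return _glcm_features(matrix)
    if kind == "glrlm":
        return _run_or_zone_features(matrix, GLRLM_FEATURES, matrix.n_voxels)
    if kind == "glszm":
        return _run_or_zone_features(matrix, GLSZM_FEATURES, matrix.n_voxels)
    raise ValueError(f"unknown texture matrix kind {kind!r}")


def average_feature_dicts(dicts: list[dict[str, float]]) -> dict[str, float]:
    """Element-wise mean of per-direction feature dicts (IBSI averaging)."""
    keys = list(dicts[0].keys())
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}
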