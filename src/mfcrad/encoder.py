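"""Deep tumor features from a frozen 3D U-Net-style convolutional encoder.

An 8x8x8 cm^3 volume of interest (VOI) centred on the tumor is normalized and
passed through five convolutional blocks (two 3x3x3 convolutions with ReLU
each; 2x max pooling after the first four blocks), carrying the channel
progression 32-64-128-256-512, and the final 512-channel feature map is
global-average-pooled into a 512-vector.  80 mm at 1 mm spacing maps
80 -> 40 -> 20 -> 10 -> 5 spatially.

The encoder is frozen: only the forward pass is implemented (float32 GEMM
convolutions).  Weights are loaded from a named-tensor ``.npz`` archive or
initialized reproducibly from a seed, so the pipeline runs end-to-end with no
external checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "EncoderConfig",
    "AugmentationSpec",
    "UNetEncoder",
    "crop_voi",
    "normalize_input",
    "augment_3d",
    "random_weights",
    "save_weights",
    "load_pretrained",
]

PAD_HU = -1000.0


@dataclass
class EncoderConfig:
    """Architecture and input-normalization settings."""

    voi_mm: int = 80
    channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    convs_per_block: int = 2
    kernel: int = 3
    hu_window: tuple[float, float] = (-1000.0, 1000.0)

    def __post_init__(self) -> None:
        n_pool = len(self.channels) - 1
        if self.voi_mm % (2**n_pool) != 0:
            raise ValueError(
                f"input grid {self.voi_mm} not divisible by 2^{n_pool}"
            )
        if self.channels[-1] != 512:
            raise ValueError("final channel count must be 512")

    def layer_shapes(self) -> dict[str, tuple[tuple[int, ...], tuple[int, ...]]]:
        """Expected (kernel, bias) shapes per layer name."""
        shapes = {}
        c_in = 1
        k = self.kernel
        for b, c_out in enumerate(self.channels, start=1):
            for conv in range(1, self.convs_per_block + 1):
                shapes[f"block{b}_conv{conv}"] = ((k, k, k, c_in, c_out), (c_out,))
                c_in = c_out
        return shapes


@dataclass
class AugmentationSpec:
    """3D augmentation sampling ranges (applied to normalized blocks)."""

    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    flip_axes: tuple[int, ...] = (0, 1, 2)
    noise_sd: float = 0.01
    multiplicity: int = 4

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


def crop_voi(volume: CTVolume, mask: np.ndarray, voi_mm: int = 80) -> np.ndarray:
    """Crop the cubic VOI centred on the mask centroid from a 1 mm grid.

    Regions outside the volume are padded at -1000 HU.  Fails explicitly when
    the tumor bounding box exceeds the VOI along any axis.
    """
    mask = np.asarray(mask)
    if mask.shape != volume.shape:
        raise ValueError("mask/volume shape mismatch")
    if not np.any(mask):
        raise ValueError("mask is empty")
    idx = np.argwhere(mask > 0)
    bbox = idx.max(axis=0) - idx.min(axis=0) + 1
    if np.any(bbox > voi_mm):
        raise ValueError(
            f"GTV bounding box {tuple(bbox)} voxels exceeds the {voi_mm} mm VOI"
        )
    centroid = np.round(idx.mean(axis=0)).astype(int)
    half = voi_mm // 2
    out = np.full((voi_mm,) * 3, PAD_HU, dtype=np.float32)
    src_lo = centroid - half
    src_hi = centroid + half
    clip_lo = np.maximum(src_lo, 0)
    clip_hi = np.minimum(src_hi, volume.shape)
    dst_lo = clip_lo - src_lo
    dst_hi = dst_lo + (clip_hi - clip_lo)
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = volume.voxels[
        clip_lo[0]:clip_hi[0], clip_lo[1]:clip_hi[1], clip_lo[2]:clip_hi[2]
    ]
    return out


def normalize_input(block: np.ndarray, hu_window: tuple[float, float] = (-1000.0, 1000.0)) -> np.ndarray:
    """Clip HU to the window and map linearly onto [0, 1]."""
    lo, hi = hu_window
    return ((np.clip(block, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def augment_3d(block: np.ndarray, spec: AugmentationSpec, seed: int = 0) -> list[np.ndarray]:
    """Sampled 3D augmentations of a normalized block.

    Returns ``spec.multiplicity`` blocks; the first is the unmodified input.
    Each remaining block applies an independently sampled rotation, isotropic
    scaling, axis flips and additive Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    out = [block.copy()]
    for _ in range(spec.multiplicity - 1):
        b = block.astype(np.float32)
        angle = rng.uniform(-spec.rotation_deg, spec.rotation_deg)
        if angle != 0.0:
            axes = tuple(rng.choice(3, size=2, replace=False).tolist())
            b = ndimage.rotate(b, angle, axes=axes, reshape=False, order=1, mode="nearest")
        scale = rng.uniform(*spec.scale_range)
        if scale != 1.0:
            center = (np.array(b.shape) - 1) / 2.0
            matrix = np.eye(3) / scale
            offset = center - matrix @ center
            b = ndimage.affine_transform(b, matrix, offset=offset, order=1, mode="nearest")
        for ax in spec.flip_axes:
            if rng.uniform() < 0.5:
                b = np.flip(b, axis=ax)
        if spec.noise_sd > 0:
            b = b + rng.normal(0.0, spec.noise_sd, size=b.shape).astype(np.float32)
        out.append(np.ascontiguousarray(b, dtype=np.float32))
    return out


def random_weights(config: EncoderConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """He-normal random encoder weights, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    weights: dict[str, np.ndarray] = {}
    for name, (kshape, bshape) in config.layer_shapes().items():
        fan_in = int(np.prod(kshape[:4]))
        weights[f"{name}_kernel"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=kshape
        ).astype(np.float32)
        weights[f"{name}_bias"] = np.zeros(bshape, dtype=np.float32)
    return weights


def save_weights(weights: dict[str, np.ndarray], path: str | Path) -> Path:
    path = Path(path)
    np.savez(path, **weights)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_pretrained(path: str | Path, config: EncoderConfig | None = None) -> dict[str, np.ndarray]:
    """Load encoder weights from a named-tensor .npz archive.

    Every ``block{b}_conv{c}_kernel``/``_bias`` tensor must be present with
    the architecture's shape; the first missing or mismatched tensor is
    reported by name.
    """
    config = config or EncoderConfig()
    with np.load(path) as npz:
        avail = dict(npz)
    weights = {}
    for name, (kshape, bshape) in config.layer_shapes().items():
        for suffix, shape in (("kernel", kshape), ("bias", bshape)):
            key = f"{name}_{suffix}"
            if key not in avail:
                raise ValueError(f"weight archive {path}: missing tensor {key!r}")
            t = avail[key]
            if t.shape != shape:
                raise ValueError(
                    f"weight archive {path}: tensor {key!r} has shape {t.shape}, expected {shape}"
                )
            weights[key] = t.astype(np.float32)
    return weights


def _conv3d_relu(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """'Same'-padded 3x3x3 convolution + ReLU.

    ``x`` is (C_in, D, H, W); ``kernel`` is (3, 3, 3, C_in, C_out).  For a
    single input channel the patch tensor is small, so a full im2col GEMM is
    used; otherwise the convolution is a sum of 27 shifted channel-mixing
    GEMMs, which keeps memory flat and stays in BLAS.
    """
    c_in, d, h, w = x.shape
    k = kernel.shape[0]
    c_out = kernel.shape[-1]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    n = d * h * w
    if c_in == 1:
        win = np.lib.stride_tricks.sliding_window_view(xp[0], (k, k, k))
        patches = win.reshape(n, k * k * k)
        kmat = kernel[:, :, :, 0, :].reshape(k * k * k, c_out)
        out = patches @ kmat
        out += bias
    else:
        out = np.tile(bias.astype(np.float32), (n, 1))
        tmp = np.empty((n, c_out), dtype=np.float32)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    patch = xp[:, dz:dz + d, dy:dy + h, dx:dx + w].reshape(c_in, n)
                    np.matmul(patch.T, kernel[dz, dy, dx], out=tmp)
                    out += tmp
    np.maximum(out, 0.0, out=out)
    return np.ascontiguousarray(out.T.reshape(c_out, d, h, w))


def _maxpool2(x: np.ndarray) -> np.ndarray:
    c, d, h, w = x.shape
    return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).max(axis=(2, 4, 6))


class UNetEncoder:
    """Frozen 5-block convolutional encoder with global average pooling."""

    def __init__(
        self,
        config: EncoderConfig | None = None,
        weights: dict[str, np.ndarray] | None = None,
        seed: int = 0,
    ):
        self.config = config or EncoderConfig()
        if weights is None:
            weights = random_weights(self.config, seed=seed)
        self._check_weights(weights)
        self.weights = weights

    def _check_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, (kshape, bshape) in self.config.layer_shapes().items():
            for suffix, shape in (("kernel", kshape), ("bias", bshape)):
                key = f"{name}_{suffix}"
                if key not in weights:
                    raise ValueError(f"missing weight tensor {key!r}")
                if tuple(weights[key].shape) != shape:
                    raise ValueError(
                        f"weight tensor {key!r} has shape {weights[key].shape}, expected {shape}"
                    )

    @classmethod
    def from_file(cls, path: str | Path, config: EncoderConfig | None = None) -> "UNetEncoder":
        config = config or EncoderConfig()
        return cls(config=config, weights=load_pretrained(path, config))

    def feature_map(self, block: np.ndarray) -> np.ndarray:
        """Final (512, s, s, s) feature map before pooling."""
        block = np.asarray(block, dtype=np.float32)
        if block.ndim != 3:
            raise ValueError("expected a 3D input block")
        n_pool = len(self.config.channels) - 1
        if any(s % 2**n_pool for s in block.shape):
            raise ValueError(f"input shape {block.shape} not divisible by 2^{n_pool}")
        x = block[None]  # (1, D, H, W)
        for b in range(1, len(self.config.channels) + 1):
            for conv in range(1, self.config.convs_per_block + 1):
                name = f"block{b}_conv{conv}"
                x = _conv3d_relu(x, self.weights[f"{name}_kernel"], self.weights[f"{name}_bias"])
            if b < len(self.config.channels):
                x = _maxpool2(x)
        return x

    def encode(self, block: np.ndarray) -> np.ndarray:
        """Global-average-pooled 512-vector for one normalized block."""
        fm = self.feature_map(block)
        return fm.mean(axis=(1, 2, 3)).astype(np.float64)


def encode_deep_features(
    block: np.ndarray, config: EncoderConfig | None = None, weights=None, seed: int = 0
) -> np.ndarray:
    """One-shot convenience wrapper: block -> 512-vector."""
    return UNetEncoder(config=config, weights=weights, seed=seed).encode(block)
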