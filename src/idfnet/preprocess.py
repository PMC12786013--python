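"""Image preprocessing operators: class-rebalancing sampling weights,
min-max and z-score normalization, Hounsfield-unit windowing, Reinhard
stain normalization (LAB colour transfer), tissue-fraction patch filtering,
and a seeded augmentation pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color

logger = logging.getLogger(__name__)

HU_CLIP = (-150.0, 350.0)


# --------------------------------------------------------------------------
# class balance / normalization
# --------------------------------------------------------------------------


@dataclass
class ClassBalance:
    class_ids: np.ndarray
    class_counts: np.ndarray
    sampling_weights: np.ndarray
    sampling_probabilities: np.ndarray


def rws_weights(class_counts) -> ClassBalance:
    """Random-weighted-sampling weights, inversely proportional to class size.

    W_i = 1 / N_i; probabilities are the weights normalized to sum to 1.
    """
    counts = np.asarray(class_counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("class_counts must be a non-empty 1-D sequence")
    if np.any(counts <= 0):
        raise ValueError("every class count must be > 0 for inverse-frequency weights")
    weights = 1.0 / counts
    return ClassBalance(
        class_ids=np.arange(counts.size),
        class_counts=counts,
        sampling_weights=weights,
        sampling_probabilities=weights / weights.sum(),
    )


@dataclass
class ChannelStats:
    mean: np.ndarray
    std: np.ndarray
    min: np.ndarray | None = None
    max: np.ndarray | None = None

    @classmethod
    def from_values(cls, values, axis=None) -> "ChannelStats":
        v = np.asarray(values, dtype=float)
        return cls(
            mean=v.mean(axis=axis),
            std=v.std(axis=axis),
            min=v.min(axis=axis),
            max=v.max(axis=axis),
        )


def minmax_normalize(values) -> np.ndarray:
    """Scale values linearly to [0, 1]; constant input is rejected."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("min-max normalization undefined for constant input (max == min)")
    return (v - lo) / (hi - lo)


def zscore(values, stats: ChannelStats | None = None) -> np.ndarray:
    """Standardize to zero mean / unit variance using ``stats`` (or the
    values' own statistics when ``stats`` is None)."""
    v = np.asarray(values, dtype=float)
    if stats is None:
        stats = ChannelStats.from_values(v)
    std = np.asarray(stats.std, dtype=float)
    if np.any(std <= 0):
        raise ValueError("z-score undefined for zero standard deviation")
    return (v - stats.mean) / std


def clip_and_scale_hu(ct_image, clip=HU_CLIP) -> np.ndarray:
    """Clip CT intensities to the soft-tissue HU window and map to [0, 1]."""
    lo, hi = clip
    v = np.clip(np.asarray(ct_image, dtype=float), lo, hi)
    return (v - lo) / (hi - lo)


# --------------------------------------------------------------------------
# Reinhard stain normalization
# --------------------------------------------------------------------------


def lab_stats(rgb_image) -> ChannelStats:
    """Per-channel mean/sd of an RGB image in LAB space (D65 illuminant)."""
    arr = np.asarray(rgb_image)
    if arr.dtype == np.uint8:
        arr = arr / 255.0
    lab = color.rgb2lab(arr)
    return ChannelStats(mean=lab.reshape(-1, 3).mean(axis=0), std=lab.reshape(-1, 3).std(axis=0))


def reinhard_normalize(source_rgb, target: ChannelStats) -> np.ndarray:
    """Colour-transfer stain normalization: match LAB channel mean/sd.

    The source is converted to LAB, each channel shifted and scaled so its
    statistics equal the target's, then converted back to RGB and clipped to
    the valid range.  A degenerate source channel (zero spread) is left at
    the target mean.  Returns float RGB in [0, 1] (uint8 input accepted).
    """
    arr = np.asarray(source_rgb)
    was_u8 = arr.dtype == np.uint8
    if was_u8:
        arr = arr / 255.0
    t_std = np.asarray(target.std, dtype=float)
    if np.any(t_std <= 0):
        raise ValueError("target LAB standard deviations must be > 0")
    lab = color.rgb2lab(arr)
    flat = lab.reshape(-1, 3)
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    out = np.empty_like(flat)
    for c in range(3):
        if sd[c] <= 1e-12:
            logger.warning("degenerate source channel %d in Reinhard transfer; set to target mean", c)
            out[:, c] = target.mean[c]
        else:
            out[:, c] = (flat[:, c] - mu[c]) / sd[c] * t_std[c] + target.mean[c]
    rgb = np.clip(color.lab2rgb(out.reshape(lab.shape)), 0.0, 1.0)
    return np.round(rgb * 255).astype(np.uint8) if was_u8 else rgb


def foreground_fraction(patch_rgb, background_threshold: float = 0.85) -> float:
    """Fraction of pixels darker than a near-white background level."""
    arr = np.asarray(patch_rgb, dtype=float)
    if arr.dtype == np.uint8 or arr.max() > 1.5:
        arr = arr / 255.0
    gray = arr.mean(axis=-1)
    return float((gray < background_threshold).mean())


def tissue_filter(patches, min_fraction: float = 0.5, background_threshold: float = 0.85):
    """Keep patches whose tissue (non-background) fraction exceeds ``min_fraction``."""
    keep = [
        i
        for i, p in enumerate(patches)
        if foreground_fraction(p, background_threshold) > min_fraction
    ]
    return keep


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------


@dataclass
class AugmentConfig:
    """Seeded augmentation menu. All magnitudes are non-negative; a zeroed
    config is the identity transform."""

    rotation_deg: float = 0.0
    horizontal_flip: bool = False
    vertical_flip: bool = False
    brightness_jitter: float = 0.0  # fraction, e.g. 0.1 => ±10 %
    contrast_jitter: float = 0.0
    blur_sigma: float = 0.0
    noise_scale: float = 0.0

    def __post_init__(self):
        for f in ("rotation_deg", "brightness_jitter", "contrast_jitter", "blur_sigma", "noise_scale"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


# the two printed augmentation menus: an endoscopy-specific recipe
# (±15° rotations, flips, brightness/contrast, blur σ=0.5) and a generic one
# (±20° rotations, flips, Gaussian noise, ±10 % contrast jitter)
PRESETS = {
    "endoscopy_paper": AugmentConfig(
        rotation_deg=15.0,
        horizontal_flip=True,
        vertical_flip=True,
        brightness_jitter=0.1,
        contrast_jitter=0.1,
        blur_sigma=0.5,
    ),
    "generic_paper": AugmentConfig(
        rotation_deg=20.0,
        horizontal_flip=True,
        vertical_flip=True,
        contrast_jitter=0.1,
        noise_scale=0.02,
    ),
}


def augment(image, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply the seeded augmentation pipeline to a float image in [0, 1]
    (2-D or H×W×C). Output has the same shape and value range."""
    img = np.asarray(image, dtype=float).copy()
    spatial_axes = (0, 1)
    if config.rotation_deg > 0:
        angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
        img = ndimage.rotate(
            img, angle, axes=(spatial_axes[1], spatial_axes[0]), reshape=False,
            order=1, mode="nearest",
        )
    if config.horizontal_flip and rng.random() < 0.5:
        img = img[:, ::-1].copy()
    if config.vertical_flip and rng.random() < 0.5:
        img = img[::-1].copy()
    if config.brightness_jitter > 0:
        img = img + rng.uniform(-config.brightness_jitter, config.brightness_jitter)
    if config.contrast_jitter > 0:
        factor = 1.0 + rng.uniform(-config.contrast_jitter, config.contrast_jitter)
        mean = img.mean()
        img = (img - mean) * factor + mean
    if config.blur_sigma > 0:
        sigma = [config.blur_sigma] * 2 + [0] * (img.ndim - 2)
        img = ndimage.gaussian_filter(img, sigma=sigma)
    if config.noise_scale > 0:
        img = img + rng.normal(0.0, config.noise_scale, size=img.shape)
    return np.clip(img, 0.0, 1.0)
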