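"""Image conditioning for radiograph/mask pairs.

The chain applied before training is fixed: resize to the working resolution,
Gaussian denoise, histogram-based intensity normalization; masks are resized
with nearest-neighbor interpolation and re-binarized so they stay {0, 1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import exposure
from skimage.transform import resize as _sk_resize

logger = logging.getLogger("unetbench")

__all__ = [
    "SegmentationPair",
    "resize_pair",
    "gaussian_kernel",
    "gaussian_denoise",
    "normalize_intensity",
    "binarize_mask",
    "preprocess_pair",
]

CLASS_LABELS = ("COVID", "Normal", "Viral Pneumonia", "synthetic")


@dataclass
class SegmentationPair:
    """One grayscale image plus its binary lung mask, sharing geometry."""

    image: np.ndarray
    mask: np.ndarray
    identifier: str = ""
    class_label: str = "synthetic"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 2 or self.mask.ndim != 2:
            raise ValueError("image and mask must be 2-D arrays")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} shapes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary (0/1)")
        self.mask = self.mask.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


def resize_pair(pair: SegmentationPair, size: tuple[int, int]) -> SegmentationPair:
    """Resample to ``size``: bilinear for the image, nearest for the mask.

    Nearest-neighbor plus re-binarization guarantees the mask stays {0, 1}
    (bilinear would smear fractional values along lung boundaries).
    """
    h, w = size
    if h < 1 or w < 1:
        raise ValueError("target size must be positive")
    if pair.image.size == 0:
        raise ValueError("cannot resize an empty image")
    if pair.shape == (h, w):
        return replace(pair)
    image = _sk_resize(pair.image, (h, w), order=1, anti_aliasing=False,
                       preserve_range=True)
    mask = _sk_resize(pair.mask.astype(np.float64), (h, w), order=0,
                      anti_aliasing=False, preserve_range=True)
    return replace(pair, image=image, mask=(mask > 0.5).astype(np.uint8))


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Discretized, sum-normalized 2-D Gaussian ``exp(-(i^2+j^2)/(2 sigma^2))``."""
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be odd and positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = size // 2
    ii, jj = np.mgrid[-r : r + 1, -r : r + 1]
    with np.errstate(under="ignore"):
        k = np.exp(-(ii**2 + jj**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_denoise(image: np.ndarray, kernel: int = 3, sigma: float = 0.5) -> np.ndarray:
    """Convolve with a normalized Gaussian; borders handled by edge replication."""
    image = np.asarray(image, dtype=np.float64)
    k = gaussian_kernel(kernel, sigma)
    return ndimage.convolve(image, k, mode="nearest")


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Histogram equalization followed by min-max scaling to [0, 1].

    The equalization maps each pixel to the empirical CDF of its value
    (the fine-binned limit of 256-bin equalization; identical to it for 8-bit
    input). The composition is exactly idempotent: an already-equalized image
    maps to itself. A constant image carries no contrast to stretch and
    passes through as all zeros.
    """
    image = np.asarray(image, dtype=np.float64)
    values, inverse, counts = np.unique(image, return_inverse=True, return_counts=True)
    if values.size == 1:
        logger.warning("normalize_intensity: constant image, returning zeros")
        return np.zeros_like(image)
    cdf = np.cumsum(counts) / image.size
    out = cdf[inverse].reshape(image.shape)
    lo, hi = out.min(), out.max()
    return (out - lo) / (hi - lo)


def equalize_adapthist(image: np.ndarray, clip_limit: float = 0.01) -> np.ndarray:
    """Optional CLAHE alternative to global equalization (not the default)."""
    out = exposure.equalize_adapthist(np.clip(image, 0, 1), clip_limit=clip_limit)
    lo, hi = out.min(), out.max()
    return (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)


def binarize_mask(mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a stored mask (8-bit, 16-bit or float) to {0, 1}.

    ``threshold`` is a fraction of the dtype's value range; values strictly
    above ``threshold * max_range`` become foreground.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    mask = np.asarray(mask)
    if np.issubdtype(mask.dtype, np.integer):
        max_range = float(np.iinfo(mask.dtype).max)
    else:
        max_range = 1.0
    out = (mask.astype(np.float64) > threshold * max_range).astype(np.uint8)
    if out.size and not out.any():
        logger.warning("binarize_mask: empty foreground")
    return out


def preprocess_pair(pair: SegmentationPair, size: tuple[int, int],
                    kernel: int = 3, sigma: float = 0.5) -> SegmentationPair:
    """Full conditioning chain: resize -> Gaussian denoise -> normalize."""
    pair = resize_pair(pair, size)
    image = gaussian_denoise(pair.image, kernel, sigma)
    image = normalize_intensity(image)
    return replace(pair, image=image)
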