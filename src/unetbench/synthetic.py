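"""Seeded chest-radiograph phantoms with exact ground-truth lung masks.

Each phantom is a bright thoracic background with two darker, vertically
elongated elliptical lung fields, optional sinusoidal rib stripes and
additive Gaussian noise. Realism is deliberately minimal — enough to give a
segmentation network a learnable figure/ground task with analytically known
masks, not to mimic pathology. The generator is pure: all randomness comes
from a local generator derived from the seed, and identical parameters give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocess import SegmentationPair

__all__ = ["PhantomParams", "generate_phantom", "generate_dataset"]

DEFAULT_CLASSES = ("COVID", "Normal", "Viral Pneumonia")


@dataclass(frozen=True)
class PhantomParams:
    """Knobs of the phantom generator.

    ``lung_axes_range`` bounds the horizontal semi-axis of each lung as a
    fraction of image width; the vertical semi-axis is that times
    ``lung_eccentricity``. ``lung_contrast`` is how much darker the lung
    fields are than ``background_level`` (both in [0, 1] intensity units).
    ``rib_amplitude`` scales horizontal sinusoidal stripes with ``rib_count``
    periods; ``noise_sigma`` is the additive Gaussian noise scale.
    """

    size: tuple[int, int] = (256, 256)
    lung_axes_range: tuple[float, float] = (0.10, 0.16)
    lung_eccentricity: float = 1.8
    rib_count: int = 6
    rib_amplitude: float = 0.04
    noise_sigma: float = 0.04
    background_level: float = 0.80
    lung_contrast: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lung_axes_range
        if not 0 < lo <= hi:
            raise ValueError("lung_axes_range must satisfy 0 < lo <= hi")
        if self.lung_eccentricity <= 0:
            raise ValueError("lung_eccentricity must be positive")
        if self.noise_sigma < 0 or self.rib_amplitude < 0:
            raise ValueError("noise_sigma and rib_amplitude must be >= 0")
        if not 0 <= self.background_level <= 1:
            raise ValueError("background_level must be in [0, 1]")
        if not 0 <= self.lung_contrast <= self.background_level:
            raise ValueError("lung_contrast must be in [0, background_level]")


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float,
                  ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def generate_phantom(params: PhantomParams,
                     identifier: str | None = None,
                     class_label: str = "synthetic") -> SegmentationPair:
    """Generate one phantom pair from ``params`` (deterministic in the seed)."""
    rng = np.random.default_rng(params.seed)
    h, w = params.size
    lo, hi = params.lung_axes_range

    # horizontal semi-axes (px) and jittered centers for the two lung fields
    ax1, ax2 = rng.uniform(lo, hi, size=2) * w
    ay1, ay2 = ax1 * params.lung_eccentricity, ax2 * params.lung_eccentricity
    cx1 = 0.31 * w + rng.uniform(-0.015, 0.015) * w
    cx2 = 0.69 * w + rng.uniform(-0.015, 0.015) * w
    cy1 = 0.50 * h + rng.uniform(-0.02, 0.02) * h
    cy2 = 0.50 * h + rng.uniform(-0.02, 0.02) * h

    if cx1 + ax1 >= cx2 - ax2 - 1:
        raise ValueError("lung axes too large to place two disjoint lung fields")
    if cx1 - ax1 < 0 or cx2 + ax2 >= w or min(cy1 - ay1, cy2 - ay2) < 0 or \
            max(cy1 + ay1, cy2 + ay2) >= h:
        raise ValueError("lung fields exceed the image; shrink lung_axes_range")

    left = _ellipse_mask((h, w), cy1, cx1, ay1, ax1)
    right = _ellipse_mask((h, w), cy2, cx2, ay2, ax2)
    mask = (left | right).astype(np.uint8)

    image = np.full((h, w), params.background_level, dtype=np.float64)
    image -= params.lung_contrast * mask
    if params.rib_amplitude > 0:
        yy = np.arange(h, dtype=np.float64)[:, None]
        image += params.rib_amplitude * np.sin(2 * np.pi * params.rib_count * yy / h)
    if params.noise_sigma > 0:
        image += params.noise_sigma * rng.standard_normal((h, w))
    image = np.clip(image, 0.0, 1.0)

    if identifier is None:
        identifier = f"phantom-{params.seed}"
    return SegmentationPair(image=image, mask=mask, identifier=identifier,
                            class_label=class_label)


def _child_seed(master_seed: int, index: int) -> int:
    """Per-item seed independent of dataset size (stable in the index)."""
    state = np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def generate_dataset(n: int, params: PhantomParams, out_dir: str | Path,
                     class_labels: tuple[str, ...] = DEFAULT_CLASSES) -> pd.DataFrame:
    """Write ``n`` phantom pairs in the dataset directory convention.

    Layout: ``<class>/images/<id>.png`` and ``<class>/masks/<id>.png`` (8-bit
    grayscale), classes assigned round-robin; a ``manifest.csv`` with columns
    identifier, class_label, image_path, mask_path, foreground_fraction is
    written at the root and returned as a DataFrame.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not class_labels:
        raise ValueError("need at least one class label")
    out_dir = Path(out_dir)
    rows = []
    for i in range(n):
        cls = class_labels[i % len(class_labels)]
        slug = cls.lower().replace(" ", "_")
        identifier = f"{slug}-{i:05d}"
        pair = generate_phantom(replace(params, seed=_child_seed(params.seed, i)),
                                identifier=identifier, class_label=cls)
        img_dir = out_dir / cls / "images"
        msk_dir = out_dir / cls / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        msk_dir.mkdir(parents=True, exist_ok=True)
        img_path = img_dir / f"{identifier}.png"
        msk_path = msk_dir / f"{identifier}.png"
        iio.imwrite(img_path, np.round(pair.image * 255).astype(np.uint8))
        iio.imwrite(msk_path, (pair.mask * 255).astype(np.uint8))
        rows.append({
            "identifier": identifier,
            "class_label": cls,
            "image_path": str(img_path.relative_to(out_dir)),
            "mask_path": str(msk_path.relative_to(out_dir)),
            "foreground_fraction": pair.foreground_fraction,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
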