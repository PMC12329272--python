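"""Reading paired image/mask PNG datasets in the directory convention.

Layout: ``<root>/<class>/images/*.png`` with same-named masks under
``<root>/<class>/masks/``. A ``manifest.csv`` at the root (as written by the
phantom generator) is used when present; otherwise the tree is scanned.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocess import SegmentationPair, binarize_mask

__all__ = ["read_image", "read_mask", "scan_dataset", "load_pairs"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG as floats in [0, 1]."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse an RGB(A) scan to luminance
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def read_mask(path: str | Path, threshold: float = 0.5) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return binarize_mask(arr, threshold)


def scan_dataset(root: str | Path) -> pd.DataFrame:
    """Manifest for a dataset directory (from manifest.csv or by scanning)."""
    root = Path(root)
    manifest_path = root / "manifest.csv"
    if manifest_path.exists():
        return pd.read_csv(manifest_path)
    rows = []
    for img_path in sorted(root.glob("*/images/*.png")):
        cls = img_path.parent.parent.name
        msk_path = img_path.parent.parent / "masks" / img_path.name
        if not msk_path.exists():
            raise FileNotFoundError(f"no mask for {img_path}")
        rows.append({
            "identifier": img_path.stem,
            "class_label": cls,
            "image_path": str(img_path.relative_to(root)),
            "mask_path": str(msk_path.relative_to(root)),
        })
    if not rows:
        raise FileNotFoundError(f"no <class>/images/*.png pairs under {root}")
    return pd.DataFrame(rows)


def load_pairs(manifest: pd.DataFrame, root: str | Path) -> list[SegmentationPair]:
    """Load every manifest row into a :class:`SegmentationPair`."""
    root = Path(root)
    pairs = []
    for row in manifest.itertuples():
        pairs.append(SegmentationPair(
            image=read_image(root / row.image_path),
            mask=read_mask(root / row.mask_path),
            identifier=str(row.identifier),
            class_label=str(row.class_label),
        ))
    return pairs
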