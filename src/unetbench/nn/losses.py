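"""Pixelwise binary cross-entropy on logits."""

from __future__ import annotations

import numpy as np

from .layers import sigmoid


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient with respect to the logits.

    Computed in the numerically stable form
    ``max(z, 0) - z*y + log(1 + exp(-|z|))`` so large-magnitude logits do not
    overflow. The gradient is ``(sigmoid(z) - y) / n_pixels``.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(logits) - targets.astype(logits.dtype)) / logits.size
    return float(loss.mean()), grad.astype(logits.dtype)
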