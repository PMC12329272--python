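"""U-Net construction from a :class:`~unetbench.variants.VariantSpec`.

The network is the classic symmetric encoder-decoder: each contracting stage
applies two same-padding convolutions (each optionally batch-normalized, then
ReLU) and a 2x2 max-pool; the bottleneck applies two convolutions; each
expanding stage upsamples with a stride-2 transposed convolution to the
mirrored channel count, concatenates the matching encoder feature map along
channels, and applies two convolutions; a 1x1 convolution with sigmoid
produces the mask probability map. All weights are He-uniform initialized
from a seeded generator, biases zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import (
    DTYPE,
    BatchNorm2D,
    Conv2D,
    ConvTranspose2D,
    Layer,
    MaxPool2D,
    ReLU,
    fold_batchnorm,
    sigmoid,
)
from .variants import VariantSpec, closed_form_param_count

__all__ = ["UNet", "ConvBlock", "BlockParams", "GeometryError", "build_unet", "count_parameters"]


class GeometryError(ValueError):
    """Input spatial size incompatible with the pooling pyramid."""


@dataclass
class BlockParams:
    """Symbol set of one convolution block: conv, optional frozen BN, ReLU.

    ``w_bn``/``b_bn`` are the effective affine weight and bias of the frozen
    batch normalization, derived from the learnable scale ``gamma``, shift
    ``beta`` and the batch statistics: ``w_bn = gamma / sqrt(var + eps)``,
    ``b_bn = beta - w_bn * mean``. Without batch normalization the block
    reduces to ``relu(conv(x) + bias)``.
    """

    w_conv: np.ndarray
    b_conv: np.ndarray
    gamma: np.ndarray | None = None
    beta: np.ndarray | None = None
    batch_mean: np.ndarray | None = None
    batch_var: np.ndarray | None = None
    epsilon: float = 1e-5
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.batch_var is not None and np.any(self.batch_var < 0):
            raise ValueError("batch variance must be non-negative")

    @property
    def use_batchnorm(self) -> bool:
        return self.gamma is not None

    def effective_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """(w_bn, b_bn) of the frozen batch normalization."""
        if not self.use_batchnorm:
            raise ValueError("block has no batch normalization")
        return fold_batchnorm(self.gamma, self.beta, self.batch_mean,
                              self.batch_var, self.epsilon)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the block on an (N, C, H, W) array."""
        conv = Conv2D(self.w_conv.shape[1], self.w_conv.shape[0],
                      self.w_conv.shape[2], np.random.default_rng(0))
        conv.params["w"] = self.w_conv.astype(DTYPE)
        conv.params["b"] = self.b_conv.astype(DTYPE)
        z = conv.forward(x.astype(DTYPE), train=False)
        if self.use_batchnorm:
            w_bn, b_bn = self.effective_affine()
            z = w_bn[:, None, None] * z + b_bn[:, None, None]
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")
        return np.maximum(z, 0.0)


class ConvBlock:
    """Convolution -> (optional BatchNorm) -> ReLU, with backprop."""

    def __init__(self, c_in: int, c_out: int, kernel: int, use_batchnorm: bool,
                 epsilon: float, rng: np.random.Generator):
        self.conv = Conv2D(c_in, c_out, kernel, rng)
        self.bn = BatchNorm2D(c_out, epsilon) if use_batchnorm else None
        self.act = ReLU()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = self.conv.forward(x, train)
        if self.bn is not None:
            x = self.bn.forward(x, train)
        return self.act.forward(x, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.act.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.conv.backward(dy)

    def layers(self) -> list[Layer]:
        return [self.conv] + ([self.bn] if self.bn is not None else [])


class UNet:
    """A built segmentation network for one variant specification.

    Use :func:`build_unet` (or ``UNet(spec, seed=...)``) to construct.
    ``predict`` returns sigmoid probabilities in (0, 1); ``forward_logits`` /
    ``backward`` expose the pre-sigmoid pass for training.
    """

    def __init__(self, spec: VariantSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        k, bn, eps = spec.conv_kernel, spec.use_batchnorm, spec.bn_epsilon

        self.encoder: list[tuple[ConvBlock, ConvBlock]] = []
        self.pools: list[MaxPool2D] = []
        c_prev = spec.in_channels
        for level in range(1, spec.encoder_levels + 1):
            c = spec.level_channels(level)
            self.encoder.append((ConvBlock(c_prev, c, k, bn, eps, rng),
                                 ConvBlock(c, c, k, bn, eps, rng)))
            self.pools.append(MaxPool2D())
            c_prev = c

        c_b = spec.bottleneck_channels
        self.bottleneck = (ConvBlock(c_prev, c_b, k, bn, eps, rng),
                           ConvBlock(c_b, c_b, k, bn, eps, rng))
        c_prev = c_b

        self.decoder: list[tuple[ConvTranspose2D, ConvBlock, ConvBlock]] = []
        for level in range(spec.encoder_levels, 0, -1):
            c = spec.level_channels(level)
            self.decoder.append((ConvTranspose2D(c_prev, c, spec.up_kernel, rng),
                                 ConvBlock(2 * c, c, k, bn, eps, rng),
                                 ConvBlock(c, c, k, bn, eps, rng)))
            c_prev = c

        self.head = Conv2D(c_prev, spec.out_channels, 1, rng)
        self._skip_grads: list[np.ndarray] | None = None

    # -- structure ---------------------------------------------------------

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b1, b2 in self.encoder:
            out += b1.layers() + b2.layers()
        out += self.bottleneck[0].layers() + self.bottleneck[1].layers()
        for up, b1, b2 in self.decoder:
            out.append(up)
            out += b1.layers() + b2.layers()
        out.append(self.head)
        return out

    @property
    def parameter_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers())

    def named_parameters(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": arr
                for i, layer in enumerate(self.layers())
                for name, arr in layer.params.items()}

    def named_grads(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": arr
                for i, layer in enumerate(self.layers())
                for name, arr in layer.grads.items()}

    def named_buffers(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": arr
                for i, layer in enumerate(self.layers())
                for name, arr in layer.buffers.items()}

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    # -- passes ------------------------------------------------------------

    def _check_geometry(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise GeometryError(
                f"expected (N, {self.spec.in_channels}, H, W) input, got {x.shape}")
        stride = 2**self.spec.encoder_levels
        h, w = x.shape[2], x.shape[3]
        if h % stride or w % stride:
            raise GeometryError(
                f"spatial size {h}x{w} not divisible by 2^{self.spec.encoder_levels}")

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_geometry(x)
        x = x.astype(DTYPE, copy=False)
        skips = []
        for (b1, b2), pool in zip(self.encoder, self.pools):
            x = b2.forward(b1.forward(x, train), train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck[1].forward(self.bottleneck[0].forward(x, train), train)
        for (up, b1, b2), skip in zip(self.decoder, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            x = b2.forward(b1.forward(x, train), train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        skip_grads = []
        for up, b1, b2 in reversed(self.decoder):
            dy = b1.backward(b2.backward(dy))
            c = dy.shape[1] // 2
            skip_grads.append(dy[:, :c])
            dy = up.backward(dy[:, c:])
        dy = self.bottleneck[0].backward(self.bottleneck[1].backward(dy))
        for (b1, b2), pool, dskip in zip(reversed(self.encoder),
                                         reversed(self.pools), reversed(skip_grads)):
            dy = pool.backward(dy) + dskip
            dy = b1.backward(b2.backward(dy))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Mask probabilities in (0, 1) for an (N, C, H, W) batch."""
        return sigmoid(self.forward_logits(x, train=False))

    def predict_mask(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict(x) > threshold).astype(np.uint8)

    # -- persistence -------------------------------------------------------

    def save_weights(self, path) -> None:
        """Checkpoint parameters and buffers to a .npz container."""
        arrays = {f"param/{k}": v for k, v in self.named_parameters().items()}
        arrays |= {f"buffer/{k}": v for k, v in self.named_buffers().items()}
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            params, buffers = self.named_parameters(), self.named_buffers()
            for key, arr in data.items():
                kind, name = key.split("/", 1)
                target = params if kind == "param" else buffers
                if name not in target:
                    raise KeyError(f"checkpoint key {key!r} not in model")
                target[name][...] = arr


def build_unet(spec: VariantSpec, seed: int = 0) -> UNet:
    """Build a seeded model for ``spec`` and audit it against the closed form."""
    model = UNet(spec, seed=seed)
    expected = closed_form_param_count(spec)
    actual = model.parameter_count
    if actual != expected:  # structural invariant, not a user error
        raise AssertionError(
            f"parameter audit failed for {spec.name}: built {actual}, closed form {expected}")
    return model


def count_parameters(model: UNet) -> int:
    """Total scalar learnable weights and biases (plus BN statistics)."""
    return model.parameter_count
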