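"""Declarative registry of the eight U-Net family members.

The family splits into two groups. Depth variants (U-Net7/9/11/13) keep the
classic doubling filter schedule and vary the number of encoder stages; width
variants (U-Net16/32/64/128) freeze the depth at the U-Net9 layout (four
encoder stages) and use one fixed channel count everywhere. The reported
"layer count" of a variant follows the encoder + bottleneck + decoder stage
convention: ``2 * encoder_levels + 1``.

A closed-form parameter count, :func:`closed_form_param_count`, mirrors the
exact stage layout used by the model builder with pure integer arithmetic, so
the built network can be audited against an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Iterator

__all__ = [
    "VariantSpec",
    "UnknownVariantError",
    "resolve_variant",
    "variant_names",
    "closed_form_param_count",
    "layer_table",
]


class UnknownVariantError(ValueError):
    """Raised when a variant name is not in the registry."""


@dataclass(frozen=True)
class VariantSpec:
    """Declarative description of one U-Net family member.

    Parameters
    ----------
    name : str
        Identifier for reports.
    encoder_levels : int
        Number of contracting stages, excluding the bottleneck.
    width_mode : {"doubling", "fixed"}
        "doubling": channels are ``initial_filters * 2**(i-1)`` at level ``i``
        and ``initial_filters * 2**encoder_levels`` in the bottleneck.
        "fixed": every level and the bottleneck use ``fixed_filters``.
    initial_filters, fixed_filters : int
        Channel counts for the respective width mode; the inactive one is
        ignored.
    in_channels, out_channels : int
        Image and mask channel counts (1 for grayscale radiographs and
        binary lung masks).
    use_batchnorm : bool
        Insert batch normalization after every block convolution.
    conv_kernel : int
        Spatial size of the block convolutions (square, same-padding).
    up_kernel : int
        Spatial size (= stride) of the transposed-convolution upsamplers.
    """

    name: str
    encoder_levels: int
    width_mode: str = "doubling"
    initial_filters: int = 64
    fixed_filters: int = 16
    in_channels: int = 1
    out_channels: int = 1
    use_batchnorm: bool = False
    conv_kernel: int = 3
    up_kernel: int = 2
    bn_epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.width_mode not in ("doubling", "fixed"):
            raise ValueError(f"width_mode must be 'doubling' or 'fixed', got {self.width_mode!r}")
        if self.encoder_levels < 1:
            raise ValueError("encoder_levels must be >= 1")
        for field in ("initial_filters", "fixed_filters", "in_channels", "out_channels"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")
        if self.conv_kernel < 1 or self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd and positive (same padding)")
        if self.up_kernel < 1:
            raise ValueError("up_kernel must be >= 1")

    @property
    def layer_count(self) -> int:
        """Reported layer count: encoder stages + bottleneck + decoder stages."""
        return 2 * self.encoder_levels + 1

    def level_channels(self, level: int) -> int:
        """Channels at encoder/decoder level ``level`` (1 = shallowest)."""
        if not 1 <= level <= self.encoder_levels:
            raise ValueError(f"level must be in [1, {self.encoder_levels}]")
        if self.width_mode == "doubling":
            return self.initial_filters * 2 ** (level - 1)
        return self.fixed_filters

    @property
    def bottleneck_channels(self) -> int:
        if self.width_mode == "doubling":
            return self.initial_filters * 2**self.encoder_levels
        return self.fixed_filters

    def channel_schedule(self) -> list[int]:
        """Encoder channels from shallow to deep, bottleneck last."""
        return [self.level_channels(i) for i in range(1, self.encoder_levels + 1)] + [
            self.bottleneck_channels
        ]

    def to_config(self) -> dict:
        """Plain mapping round-trippable through YAML/JSON."""
        return asdict(self)

    @classmethod
    def from_config(cls, config: dict) -> "VariantSpec":
        return cls(**config)

    def with_(self, **kwargs) -> "VariantSpec":
        return replace(self, **kwargs)


def _registry() -> dict[str, VariantSpec]:
    depth = {
        # (encoder_levels, initial_filters): the count-consistent column.
        "U-Net7": (3, 64),
        "U-Net9": (4, 32),
        "U-Net11": (5, 16),
        "U-Net13": (6, 8),
    }
    width = {"U-Net16": 16, "U-Net32": 32, "U-Net64": 64, "U-Net128": 128}
    reg: dict[str, VariantSpec] = {}
    for name, (levels, filt) in depth.items():
        reg[name] = VariantSpec(name=name, encoder_levels=levels, width_mode="doubling",
                                initial_filters=filt)
    for name, filt in width.items():
        reg[name] = VariantSpec(name=name, encoder_levels=4, width_mode="fixed",
                                fixed_filters=filt)
    return reg


_REGISTRY = _registry()
_LOOKUP = {k.lower(): v for k, v in _REGISTRY.items()}


def variant_names() -> list[str]:
    """Canonical names of the eight reference variants."""
    return list(_REGISTRY)


def resolve_variant(name: str) -> VariantSpec:
    """Look up a reference configuration by name (case-insensitive).

    Raises
    ------
    UnknownVariantError
        If ``name`` is not one of the eight registered variants.
    """
    spec = _LOOKUP.get(name.strip().lower())
    if spec is None:
        raise UnknownVariantError(
            f"unsupported variant {name!r}; valid names: {', '.join(variant_names())}"
        )
    return spec


def _conv_params(c_in: int, c_out: int, k: int) -> int:
    # weights + one bias per output channel
    return c_in * c_out * k * k + c_out


def _iter_convolutions(spec: VariantSpec) -> Iterator[tuple[str, int, int, int]]:
    """Yield (role, c_in, c_out, kernel) for every convolution in build order.

    Mirrors the exact stage layout of the model builder: per encoder level two
    block convolutions then a pool; two bottleneck convolutions; per decoder
    level one transposed convolution to the mirrored channel count followed by
    two block convolutions on the concatenated (2x channels) input; a 1x1 head.
    """
    k = spec.conv_kernel
    c_prev = spec.in_channels
    for level in range(1, spec.encoder_levels + 1):
        c = spec.level_channels(level)
        yield ("enc_conv", c_prev, c, k)
        yield ("enc_conv", c, c, k)
        c_prev = c
    c_b = spec.bottleneck_channels
    yield ("bottleneck_conv", c_prev, c_b, k)
    yield ("bottleneck_conv", c_b, c_b, k)
    c_prev = c_b
    for level in range(spec.encoder_levels, 0, -1):
        c = spec.level_channels(level)
        yield ("up_conv", c_prev, c, spec.up_kernel)
        yield ("dec_conv", 2 * c, c, k)
        yield ("dec_conv", c, c, k)
        c_prev = c
    yield ("head_conv", c_prev, spec.out_channels, 1)


def closed_form_param_count(spec: VariantSpec) -> int:
    """Pure-arithmetic parameter count for ``spec``.

    Sums ``c_in * c_out * k**2 + c_out`` over every convolution of the exact
    stage layout the builder produces. With batch normalization enabled, each
    block convolution additionally carries gamma, beta and the running
    mean/variance: 4 scalars per normalized channel.
    """
    total = 0
    for role, c_in, c_out, k in _iter_convolutions(spec):
        total += _conv_params(c_in, c_out, k)
        if spec.use_batchnorm and role in ("enc_conv", "bottleneck_conv", "dec_conv"):
            total += 4 * c_out
    return total


def layer_table(spec: VariantSpec) -> list[dict]:
    """Per-convolution audit rows: role, channels, kernel, parameters."""
    rows = []
    for role, c_in, c_out, k in _iter_convolutions(spec):
        params = _conv_params(c_in, c_out, k)
        if spec.use_batchnorm and role in ("enc_conv", "bottleneck_conv", "dec_conv"):
            params += 4 * c_out
        rows.append({"role": role, "c_in": c_in, "c_out": c_out, "kernel": k,
                     "params": params})
    return rows
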