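"""V-net: 3D encoder-decoder with residual convolution blocks.

The stem is a single strided (not residual) convolution that halves the
in-plane resolution while preserving the slice count; every deeper level
adds another ``base_filters`` filters (48, 96, 144, ... at full scale).
Downsampling uses strided 3x3x3 convolutions, upsampling uses transposed
convolutions whose kernel equals the stride; skips are concatenations. The
last transposed convolution maps to two filters, and the output layer is a
1x1x1 convolution with a sigmoid. Dropout (element-wise, rate 0.5) is
applied only in encoder residual blocks.
"""

from __future__ import annotations

import numpy as np

from ..nn import Conv3d, ConvTranspose3d, Layer, Tensor, concat
from .blocks import ConvBlock, ResConvBlock
from .config import ModelConfig, vnet_filter_plan

__all__ = ["VNet", "build_vnet"]


def _depth_strides(shape: tuple[int, int, int], levels: int) -> list[tuple[int, int, int]]:
    """Stem stride plus one stride per deeper level; depth is strided only
    while it stays divisible by two."""
    strides = [(2, 2, 1)]  # stem halves in-plane only
    h, w, d = shape[0] // 2, shape[1] // 2, shape[2]
    for _ in range(levels - 1):
        sd = 2 if d % 2 == 0 and d >= 4 else 1
        strides.append((2, 2, sd))
        if h % 2 or w % 2:
            raise ValueError(
                f"in-plane size {(h, w)} not divisible by 2 at this level; "
                f"input shape must be divisible by 2^{levels}"
            )
        h, w, d = h // 2, w // 2, d // sd
    return strides


class VNet(Layer):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        filters = vnet_filter_plan(cfg)
        self.filter_plan = list(filters)
        if cfg.input_shape[0] % (1 << cfg.levels) or cfg.input_shape[1] % (1 << cfg.levels):
            raise ValueError(
                f"input shape {cfg.input_shape} must be divisible in-plane by "
                f"2^{cfg.levels} = {1 << cfg.levels}"
            )
        strides = _depth_strides(cfg.input_shape, cfg.levels)
        self.strides = strides
        norm, rate = cfg.norm, cfg.dropout_rate

        self.stem = ConvBlock(1, filters[0], (3, 3, 3), strides[0], rng=rng, norm=norm)
        self.enc_blocks = [
            ResConvBlock(f, rng=rng, dropout_rate=rate, norm=norm) for f in filters
        ]
        self.down_convs = [
            ConvBlock(filters[i], filters[i + 1], (3, 3, 3), strides[i + 1],
                      rng=rng, norm=norm)
            for i in range(cfg.levels - 1)
        ]
        self.up_convs = [
            ConvTranspose3d(filters[i + 1], filters[i], stride=strides[i + 1], rng=rng)
            for i in reversed(range(cfg.levels - 1))
        ]
        self.merge_convs = [
            ConvBlock(2 * filters[i], filters[i], (3, 3, 3), rng=rng, norm=norm)
            for i in reversed(range(cfg.levels - 1))
        ]
        self.dec_blocks = [
            ResConvBlock(filters[i], rng=rng, dropout_rate=0.0, norm=norm)
            for i in reversed(range(cfg.levels - 1))
        ]
        self.final_up = ConvTranspose3d(filters[0], 2, stride=strides[0], rng=rng)
        self.head = Conv3d(2, 1, (1, 1, 1), rng=rng)
        self.head.bias.data[:] = cfg.head_bias()

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        skips = []
        h = self.stem(x, train=train)
        for i, block in enumerate(self.enc_blocks):
            h = block(h, train=train)
            if i < len(self.down_convs):
                skips.append(h)
                h = self.down_convs[i](h, train=train)
        for up, merge, block, skip in zip(
            self.up_convs, self.merge_convs, self.dec_blocks, reversed(skips)
        ):
            h = up(h)
            h = merge(concat([h, skip], axis=1), train=train)
            h = block(h, train=train)
        h = self.final_up(h)
        return self.head(h).sigmoid()


def build_vnet(cfg: ModelConfig, rng: np.random.Generator | None = None) -> VNet:
    return VNet(cfg, rng)
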