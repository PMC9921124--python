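"""Shared building blocks: conv-norm-activation stacks, residual blocks,
mobile inverted bottleneck (MBConv) blocks, and fast normalized fusion."""

from __future__ import annotations

import numpy as np

from ..nn import (
    BatchNorm,
    Conv3d,
    DepthwiseConv3d,
    Dropout,
    GroupNorm,
    Layer,
    PReLU,
    SqueezeExcite,
    StochasticDepth,
    Tensor,
)

__all__ = [
    "make_norm",
    "ConvBlock",
    "ResConvBlock",
    "MBConv",
    "FusionWeights",
    "fast_normalized_fusion",
    "FusionNode",
    "resize_nearest_to",
]


def make_norm(kind: str, ch: int) -> Layer:
    if kind == "batch":
        return BatchNorm(ch)
    if kind == "group":
        return GroupNorm(ch, groups=1)
    raise ValueError(f"unknown norm {kind!r}")


class ConvBlock(Layer):
    """Conv3D -> (norm) -> activation ('prelu' or 'swish')."""

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 3, 3), stride=(1, 1, 1), *,
                 rng: np.random.Generator, norm: str | None = "batch",
                 activation: str = "prelu"):
        self.conv = Conv3d(in_ch, out_ch, kernel, stride, rng=rng)
        self.norm = make_norm(norm, out_ch) if norm else None
        self.activation = activation
        self.act = PReLU(out_ch) if activation == "prelu" else None

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x, train=train)
        if self.act is not None:
            return self.act(x)
        if self.activation == "swish":
            return x.swish()
        if self.activation == "linear":
            return x
        raise ValueError(self.activation)


class ResConvBlock(Layer):
    """Residual block: PReLU(Dropout(BatchNorm(Conv3D(x)))) + x.

    Dropout is element-wise ("non-spatial") and active only when the block
    is flagged as encoder-side (rate 0.5 in the reference recipe).
    """

    def __init__(self, filters: int, *, rng: np.random.Generator,
                 dropout_rate: float = 0.0, norm: str = "batch"):
        self.filters = filters
        self.conv = Conv3d(filters, filters, (3, 3, 3), rng=rng)
        self.norm = make_norm(norm, filters)
        self.dropout = Dropout(dropout_rate, rng) if dropout_rate > 0 else None
        self.act = PReLU(filters)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        if x.shape[1] != self.filters:
            raise ValueError(f"residual block needs {self.filters} channels, got {x.shape[1]}")
        h = self.norm(self.conv(x), train=train)
        if self.dropout is not None:
            h = self.dropout(h, train=train)
        return self.act(h) + x


class MBConv(Layer):
    """Mobile inverted bottleneck convolution.

    expand (1x1 conv, skipped when expansion == 1) -> depthwise conv ->
    squeeze-and-excitation (ratio 0.25 of input channels) -> linear 1x1
    projection -> stochastic depth (rate 0.2) -> residual add when the
    spatial shape and channel count are preserved.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 3, 1), stride=(1, 1, 1), *,
                 expansion: float = 6.0, rng: np.random.Generator,
                 norm: str = "batch", sd_rate: float = 0.2):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.stride = tuple(stride)
        mid = in_ch if expansion == 1 else int(np.ceil(in_ch * expansion))
        self.expand = (
            None if expansion == 1
            else ConvBlock(in_ch, mid, (1, 1, 1), rng=rng, norm=norm, activation="swish")
        )
        self.dw = DepthwiseConv3d(mid, kernel, stride, rng=rng)
        self.dw_norm = make_norm(norm, mid)
        self.se = SqueezeExcite(mid, ratio=0.25 * in_ch / mid, rng=rng)
        self.project = Conv3d(mid, out_ch, (1, 1, 1), rng=rng)
        self.proj_norm = make_norm(norm, out_ch)
        self.sd = StochasticDepth(sd_rate, rng)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        h = x if self.expand is None else self.expand(x, train=train)
        h = self.dw_norm(self.dw(h), train=train).swish()
        h = self.se(h, train=train)
        h = self.proj_norm(self.project(h), train=train)
        if self.in_ch == self.out_ch and self.stride == (1, 1, 1):
            return self.sd(h, train=train) + x
        return h


class FusionWeights(Layer):
    """Learned fusion weights: one row per input, one column per channel
    (channel + input attention), plus the epsilon stabilizer."""

    def __init__(self, n_inputs: int, channels: int, eps: float = 1e-4):
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.omega = Tensor(np.ones((n_inputs, channels)), requires_grad=True)
        self.eps = eps


def fast_normalized_fusion(
    inputs: list[Tensor], w: FusionWeights, relu_denominator: bool = False
) -> Tensor:
    """O = sum_i ReLU(w_i) / (eps + sum_j w_j) * I_i, broadcast per channel.

    ``relu_denominator=False`` follows the printed formula (raw weights in
    the denominator); the original detection network rectifies them there
    too, which the switch restores.
    """
    n, c = w.omega.shape
    if len(inputs) != n:
        raise ValueError(f"{len(inputs)} inputs for {n} weight rows")
    for t in inputs[1:]:
        if t.shape != inputs[0].shape:
            raise ValueError("fusion inputs must share a shape")
    if inputs[0].shape[1] != c:
        raise ValueError(f"inputs have {inputs[0].shape[1]} channels, weights {c}")
    denom_terms = w.omega.relu() if relu_denominator else w.omega
    denom = denom_terms.sum(axis=0) + w.eps  # (C,)
    out = None
    for i, t in enumerate(inputs):
        coef = (w.omega[i].relu() / denom).reshape(1, c, 1, 1, 1)
        term = t * coef
        out = term if out is None else out + term
    return out


class FusionNode(Layer):
    """One fusion stage: weighted merge of two equal-shape feature maps."""

    def __init__(self, channels: int, relu_denominator: bool = False):
        self.weights = FusionWeights(2, channels)
        self.relu_denominator = relu_denominator

    def fuse(self, a: Tensor, b: Tensor) -> Tensor:
        return fast_normalized_fusion([a, b], self.weights, self.relu_denominator)


def resize_nearest_to(x: Tensor, target_shape: tuple[int, int, int]) -> Tensor:
    """Nearest-neighbour resize up to ``target_shape`` (per-axis factor is
    ceil(target/current), then center-crop)."""
    cur = x.shape[2:]
    factors = tuple(-(-t // c) for t, c in zip(target_shape, cur))
    if any(f < 1 for f in factors):
        raise ValueError(f"cannot downscale {cur} to {target_shape} by nearest resize")
    if factors != (1, 1, 1):
        x = x.upsample_nearest(factors)
    if x.shape[2:] != tuple(target_shape):
        x = x.crop_spatial(target_shape)
    return x
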