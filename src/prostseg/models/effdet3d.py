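"""Segmentation-adapted 3D EfficientDet.

A 3D EfficientNet backbone (expansion 2.0, N x N x 3 kernels, per-level
channels {32, 24, 48, 48, 64, 80, 96}) feeds a single top-down fusion pass:
each pyramid level is first projected to a common channel dimension of 48
with 1x1x1 convolutions, then iteratively merged with the level below by
fast normalized fusion with channel+input attention. Upscaling between
levels is a nearest-neighbour resize followed by a 3x3x1 anti-aliasing
depthwise convolution; every convolution is followed by batch norm and a
swish activation except the final 1x1x1 sigmoid head. There is exactly one
fusion stage per level pair — no stacked feature-pyramid layers.
"""

from __future__ import annotations

import numpy as np

from ..nn import Conv3d, DepthwiseConv3d, Layer, Tensor
from .blocks import ConvBlock, FusionNode, make_norm, resize_nearest_to
from .config import ModelConfig
from .encoder import build_efficientnet_b0_encoder

__all__ = ["EfficientDet3D", "build_efficientdet3d"]


class _UpscaleBlock(Layer):
    """Nearest-neighbour resize + 3x3x1 anti-aliasing depthwise conv."""

    def __init__(self, ch: int, norm: str, rng: np.random.Generator):
        self.conv = DepthwiseConv3d(ch, (3, 3, 1), rng=rng)
        self.norm = make_norm(norm, ch)

    def __call__(self, x: Tensor, target_shape, train: bool = False) -> Tensor:
        x = resize_nearest_to(x, target_shape)
        return self.norm(self.conv(x), train=train).swish()


class _PostFuseBlock(Layer):
    """Depthwise conv + norm + swish applied after each fusion."""

    def __init__(self, ch: int, norm: str, rng: np.random.Generator):
        self.conv = DepthwiseConv3d(ch, (3, 3, 3), rng=rng)
        self.norm = make_norm(norm, ch)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return self.norm(self.conv(x), train=train).swish()


class EfficientDet3D(Layer):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.backbone = build_efficientnet_b0_encoder(cfg, dims="3d", in_ch=1, rng=rng)
        self.level_channels = list(self.backbone.level_channels)
        fused = cfg.fused_channels
        self.fused_channels = fused
        norm = cfg.norm
        n = len(self.level_channels)
        self.projections = [
            ConvBlock(c, fused, (1, 1, 1), rng=rng, norm=norm, activation="swish")
            for c in self.level_channels
        ]
        # one fusion node per level pair, deepest first
        self.fusion_nodes = [
            FusionNode(fused, cfg.fusion_relu_denominator) for _ in range(n - 1)
        ]
        self.upscales = [_UpscaleBlock(fused, norm, rng) for _ in range(n - 1)]
        self.post_fuse = [_PostFuseBlock(fused, norm, rng) for _ in range(n - 1)]
        self.final_up = _UpscaleBlock(fused, norm, rng)
        self.head = Conv3d(fused, 1, (1, 1, 1), rng=rng)
        self.head.bias.data[:] = cfg.head_bias()

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        full_shape = x.shape[2:]
        feats = self.backbone(x, train=train)
        proj = [p(f, train=train) for p, f in zip(self.projections, feats)]
        y = proj[-1]
        for up, node, post, lower in zip(
            self.upscales, self.fusion_nodes, self.post_fuse, reversed(proj[:-1])
        ):
            y = up(y, lower.shape[2:], train=train)
            y = node.fuse(y, lower)
            y = post(y, train=train)
        y = self.final_up(y, full_shape, train=train)
        return self.head(y).sigmoid()


def build_efficientdet3d(cfg: ModelConfig, rng: np.random.Generator | None = None) -> EfficientDet3D:
    return EfficientDet3D(cfg, rng)
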