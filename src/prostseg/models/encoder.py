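"""EfficientNetB0-style encoders emitting feature pyramids.

The 2D variant processes volumes slice-by-slice — expressed here as 3D
convolutions with (k, k, 1) kernels and (s, s, 1) strides, which is exactly
per-slice 2D convolution. The 3D variant used by the segmentation-adapted
detector replaces N x N kernels (N != 1) with N x N x 3 ones, sets the MBConv
expansion factor to 2.0, and uses per-level output channels
{32, 24, 48, 48, 64, 80, 96} for P1..P7. Depth is strided alongside the
plane only while it remains divisible by two.
"""

from __future__ import annotations

import numpy as np

from ..nn import Layer, Tensor
from .blocks import ConvBlock, MBConv
from .config import EFFICIENTNET_B0_STAGES, ModelConfig, effdet3d_level_channels

__all__ = ["EfficientNetEncoder", "build_efficientnet_b0_encoder"]

# kernel sizes per pyramid level P2..P7 in the 3D variant
_EFFDET3D_KERNELS = (3, 3, 3, 5, 5, 3)


class EfficientNetEncoder(Layer):
    """Backbone returning a list of pyramid features, shallow to deep.

    ``level_channels[i]`` is the channel count of the feature at in-plane
    stride ``2**(i+1)``.
    """

    def __init__(self, in_ch: int, cfg: ModelConfig, dims: str, *, rng: np.random.Generator):
        if dims not in ("2d", "3d"):
            raise ValueError(f"dims must be '2d' or '3d', got {dims!r}")
        self.dims = dims
        norm = cfg.norm
        sd = 0.2
        self.units: list[tuple[Layer, bool]] = []  # (block, closes a pyramid level)
        self.level_channels: list[int] = []

        def kern(k: int) -> tuple[int, int, int]:
            return (k, k, 3 if dims == "3d" and k != 1 else 1)

        depth = cfg.input_shape[2]

        def stride2() -> tuple[int, int, int]:
            nonlocal depth
            if dims == "3d" and depth % 2 == 0 and depth >= 4:
                depth //= 2
                return (2, 2, 2)
            return (2, 2, 1)

        if dims == "2d":
            stem_ch = cfg.scaled(32)
            self.stem = ConvBlock(in_ch, stem_ch, kern(3), stride2(), rng=rng,
                                  norm=norm, activation="swish")
            ch = stem_ch
            level = 1
            for repeats, k, out_ch, stage_stride, expansion in EFFICIENTNET_B0_STAGES:
                if level > cfg.levels:
                    break
                if stage_stride == 2:
                    level += 1
                    if level > cfg.levels:
                        break
                out_ch = cfg.scaled(out_ch)
                reps = max(1, int(round(repeats * min(cfg.scale, 1.0))))
                for r in range(reps):
                    stride = stride2() if (r == 0 and stage_stride == 2) else (1, 1, 1)
                    self.units.append(
                        (MBConv(ch, out_ch, kern(k), stride, expansion=expansion,
                                rng=rng, norm=norm, sd_rate=sd), False)
                    )
                    ch = out_ch
                self.units[-1] = (self.units[-1][0], True)
            self._finalize_levels(stem_ch)
        else:
            plan = effdet3d_level_channels(cfg)
            stem_ch = plan[0]
            self.stem = ConvBlock(in_ch, stem_ch, kern(3), (2, 2, 1), rng=rng,
                                  norm=norm, activation="swish")
            ch = stem_ch
            for i, out_ch in enumerate(plan[1:]):
                k = _EFFDET3D_KERNELS[min(i, len(_EFFDET3D_KERNELS) - 1)]
                self.units.append(
                    (MBConv(ch, out_ch, kern(k), stride2(),
                            expansion=cfg.expansion_factor, rng=rng, norm=norm,
                            sd_rate=sd), True)
                )
                ch = out_ch
            self._finalize_levels(stem_ch)

    def _finalize_levels(self, stem_ch: int) -> None:
        # mirror the forward walk: a strided block opens a new level, any
        # later block overwrites the channel count of the current level
        chans = [stem_ch]
        for block, _ in self.units:
            if block.stride[0] == 2:
                chans.append(block.out_ch)
            else:
                chans[-1] = block.out_ch
        self.level_channels = chans

    def __call__(self, x: Tensor, train: bool = False) -> list[Tensor]:
        feats: list[Tensor] = []
        x = self.stem(x, train=train)
        feats.append(x)
        for block, _ in self.units:
            if block.stride[0] == 2:
                feats.append(None)  # placeholder for the new level
            x = block(x, train=train)
            feats[-1] = x
        return feats


def build_efficientnet_b0_encoder(
    cfg: ModelConfig, dims: str, in_ch: int = 3, rng: np.random.Generator | None = None
) -> EfficientNetEncoder:
    """Build the encoder; ``dims='2d'`` for the slice-wise transfer model,
    ``'3d'`` for the segmentation-adapted detector backbone."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return EfficientNetEncoder(in_ch, cfg, dims, rng=rng)
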