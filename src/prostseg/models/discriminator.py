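"""GAN discriminator: a volume classifier over concatenated mask pairs.

The ground-truth and generated masks are concatenated on the channel axis
and passed through consecutive strided convolution blocks (4x4x4 kernels,
PReLU, batch norm on every block except the first), one regular convolution
block, element-wise dropout (rate 0.5), and a final linear dense layer that
emits one scalar score per pair.
"""

from __future__ import annotations

import numpy as np

from ..nn import Dense, Dropout, Layer, Tensor, concat
from .blocks import ConvBlock
from .config import ModelConfig

__all__ = ["Discriminator", "build_discriminator"]


class Discriminator(Layer):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        levels = cfg.levels
        base = cfg.scaled(cfg.extras.get("disc_base_filters", 64))
        h, w, d = cfg.input_shape
        self.blocks: list[ConvBlock] = []
        ch = 2
        for i in range(levels):
            sd = 2 if d % 2 == 0 and d >= 4 else 1
            out_ch = base * (1 << min(i, 3))
            self.blocks.append(
                ConvBlock(ch, out_ch, (4, 4, 4), (2, 2, sd), rng=rng,
                          norm=None if i == 0 else cfg.norm)
            )
            ch = out_ch
            h, w, d = -(-h // 2), -(-w // 2), -(-d // sd)
        self.blocks.append(ConvBlock(ch, ch, (4, 4, 4), (1, 1, 1), rng=rng, norm=cfg.norm))
        self.dropout = Dropout(cfg.dropout_rate, rng)
        self.dense = Dense(ch * h * w * d, 1, rng=rng)
        self._flat = (ch * h * w * d,)

    def __call__(self, real: Tensor, fake: Tensor | None = None, train: bool = False) -> Tensor:
        """Score a (real, generated) mask pair; returns shape (batch, 1)."""
        if fake is not None:
            if real.shape != fake.shape:
                raise ValueError(f"mask shapes differ: {real.shape} vs {fake.shape}")
            x = concat([real, fake], axis=1)
        else:
            x = real  # already concatenated
        for block in self.blocks:
            x = block(x, train=train)
        x = self.dropout(x, train=train)
        x = x.reshape(x.shape[0], -1)
        if x.shape[1] != self._flat[0]:
            raise ValueError(
                f"input spatial shape does not match the configured {self._flat[0]} features"
            )
        return self.dense(x)


def build_discriminator(cfg: ModelConfig, rng: np.random.Generator | None = None) -> Discriminator:
    return Discriminator(cfg, rng)
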