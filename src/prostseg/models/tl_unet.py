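"""Transfer-style U-net: slice-wise EfficientNetB0 encoder + U-net decoder.

An initial 3x3x3 convolution maps the volume to three channels (the input
format of ImageNet encoders), the result is center-cropped in-plane
(224x224 at full scale), every slice runs through the 2D encoder, a U-net
decoder with filters {360, 288, 216, 144, 72} (levels P7..P3) and 4x4
kernels restores the crop resolution, and the per-slice sigmoid outputs are
zero-padded back onto the original grid — the region outside the crop is
exactly zero.

Pretrained encoder weights can be injected via ``load_encoder_weights``;
with none given the encoder starts from seeded random init (logged).
"""

from __future__ import annotations

import logging

import numpy as np

from ..nn import Conv3d, Layer, Tensor, concat
from .blocks import ConvBlock
from .config import ModelConfig, tl_decoder_filter_plan
from .encoder import build_efficientnet_b0_encoder

__all__ = ["TLUNet", "build_tl_unet"]

log = logging.getLogger(__name__)


class TLUNet(Layer):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.input_shape = tuple(cfg.input_shape)
        self.crop = cfg.crop_size
        if self.crop > min(cfg.input_shape[:2]):
            raise ValueError(f"crop {self.crop} exceeds in-plane size {cfg.input_shape[:2]}")
        if self.crop % (1 << cfg.levels):
            raise ValueError(f"crop {self.crop} must be divisible by 2^{cfg.levels}")
        self.adapter = Conv3d(1, 3, (3, 3, 3), rng=rng)
        self.encoder = build_efficientnet_b0_encoder(cfg, dims="2d", in_ch=3, rng=rng)
        enc_ch = self.encoder.level_channels  # shallow -> deep
        self.decoder_filters = tl_decoder_filter_plan(cfg)  # deep -> shallow
        if len(self.decoder_filters) != len(enc_ch):
            raise ValueError(
                f"decoder plan {self.decoder_filters} does not match "
                f"{len(enc_ch)} encoder levels"
            )
        self.dec_blocks = []
        ch = enc_ch[-1]
        skips = enc_ch[:-1][::-1] + [0]  # deepest skip first, none at full res
        for f, skip_ch in zip(self.decoder_filters, skips):
            self.dec_blocks.append(
                ConvBlock(ch + skip_ch, f, (4, 4, 1), rng=rng, norm=cfg.norm)
            )
            ch = f
        self.head = Conv3d(ch, 1, (1, 1, 1), rng=rng)
        self.head.bias.data[:] = cfg.head_bias()

    def load_encoder_weights(self, weights: list[np.ndarray]) -> None:
        """Inject pretrained encoder weights (shape-checked, in parameter order)."""
        params = self.encoder.parameters()
        if len(weights) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            if p.shape != np.shape(w):
                raise ValueError(f"weight shape {np.shape(w)} does not match {p.shape}")
            p.data = np.asarray(w, dtype=np.float64)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        H, W, D = x.shape[2:]
        h = self.adapter(x)
        h = h.crop_spatial((self.crop, self.crop, D))
        feats = self.encoder(h, train=train)
        y = feats[-1]
        skips = feats[:-1][::-1] + [None]
        for block, skip in zip(self.dec_blocks, skips):
            y = y.upsample_nearest((2, 2, 1))
            if skip is not None:
                y = concat([y, skip], axis=1)
            y = block(y, train=train)
        y = self.head(y).sigmoid()
        ph, pw = (H - self.crop) // 2, (W - self.crop) // 2
        return y.pad_spatial(((ph, H - self.crop - ph), (pw, W - self.crop - pw), (0, 0)))


def build_tl_unet(
    cfg: ModelConfig,
    rng: np.random.Generator | None = None,
    pretrained: list[np.ndarray] | None = None,
) -> TLUNet:
    model = TLUNet(cfg, rng)
    if pretrained is not None:
        model.load_encoder_weights(pretrained)
    else:
        log.info("no pretrained encoder weights supplied; using seeded random init")
    return model
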