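"""Model zoo: the four segmentation architectures as configurable graphs."""

from __future__ import annotations

import numpy as np

from .blocks import (
    ConvBlock,
    FusionNode,
    FusionWeights,
    MBConv,
    ResConvBlock,
    fast_normalized_fusion,
)
from .config import (
    EFFICIENTNET_B0_STAGES,
    ModelConfig,
    default_config,
    desk_config,
    effdet3d_level_channels,
    tl_decoder_filter_plan,
    vnet_filter_plan,
)
from .discriminator import Discriminator, build_discriminator
from .effdet3d import EfficientDet3D, build_efficientdet3d
from .encoder import EfficientNetEncoder, build_efficientnet_b0_encoder
from .tl_unet import TLUNet, build_tl_unet
from .vnet import VNet, build_vnet

MODEL_ZOO = {
    "vnet": build_vnet,
    "tl_unet": build_tl_unet,
    "effdet3d": build_efficientdet3d,
    "gan": build_tl_unet,  # the GAN generator shares the transfer architecture
}


def build_model(cfg: ModelConfig, rng: np.random.Generator | None = None):
    """Build the segmentation network named by ``cfg.arch``."""
    try:
        builder = MODEL_ZOO[cfg.arch]
    except KeyError:
        raise ValueError(f"unknown architecture {cfg.arch!r}") from None
    return builder(cfg, rng)


__all__ = [
    "ModelConfig",
    "default_config",
    "desk_config",
    "vnet_filter_plan",
    "tl_decoder_filter_plan",
    "effdet3d_level_channels",
    "EFFICIENTNET_B0_STAGES",
    "MODEL_ZOO",
    "build_model",
    "build_vnet",
    "build_tl_unet",
    "build_discriminator",
    "build_efficientdet3d",
    "build_efficientnet_b0_encoder",
    "VNet",
    "TLUNet",
    "Discriminator",
    "EfficientDet3D",
    "EfficientNetEncoder",
    "ConvBlock",
    "ResConvBlock",
    "MBConv",
    "FusionWeights",
    "FusionNode",
    "fast_normalized_fusion",
]
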