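"""Scalable architecture descriptions.

A :class:`ModelConfig` reproduces the reference settings at ``scale=1`` and
shrinks filter counts / pyramid depth for desk-scale runs via the ``scale``
multiplier, so a forward+backward pass fits on one CPU. Filter plans are
computed by pure functions so structural tests can inspect them without
instantiating weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ModelConfig",
    "vnet_filter_plan",
    "tl_decoder_filter_plan",
    "effdet3d_level_channels",
    "EFFICIENTNET_B0_STAGES",
    "default_config",
    "desk_config",
]

ARCHS = ("vnet", "tl_unet", "gan", "effdet3d")

# 2D EfficientNetB0 stage plan: (repeats, kernel, out_channels, stride, expansion)
EFFICIENTNET_B0_STAGES = (
    (1, 3, 16, 1, 1.0),
    (2, 3, 24, 2, 6.0),
    (2, 5, 40, 2, 6.0),
    (3, 3, 80, 2, 6.0),
    (3, 5, 112, 1, 6.0),
    (4, 5, 192, 2, 6.0),
    (1, 3, 320, 1, 6.0),
)

# 3D segmentation-adapted variant: per-level output channels P1..P7
EFFDET3D_LEVEL_CHANNELS = (32, 24, 48, 48, 64, 80, 96)
TL_DECODER_FILTERS = (360, 288, 216, 144, 72)  # levels P7..P3


@dataclass
class ModelConfig:
    """Architecture description shared by all builders.

    ``scale`` multiplies every filter count (minimum 2) and, for the pyramid
    architectures, ``levels`` bounds the pyramid depth so small grids remain
    divisible. ``norm='group'`` is a fallback for batch-size-1 desk runs.
    """

    arch: str = "vnet"
    input_shape: tuple[int, int, int] = (320, 320, 28)
    base_filters: int = 48
    levels: int = 4
    expansion_factor: float = 2.0
    dropout_rate: float = 0.5
    fused_channels: int = 48
    crop_size: int = 224
    scale: float = 1.0
    seed: int = 0
    norm: str = "batch"
    head_bias_prior: float = 0.1  # expected foreground fraction; biases the
    # sigmoid head toward background at init so the early loss surface is not
    # dominated by a half-on prediction
    fusion_relu_denominator: bool = False  # printed form uses raw weights
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"unknown architecture {self.arch!r}; choose from {ARCHS}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.expansion_factor <= 0 or self.scale <= 0:
            raise ValueError("expansion_factor and scale must be positive")

    def scaled(self, filters: int) -> int:
        return max(2, int(round(filters * self.scale)))

    def head_bias(self) -> float:
        """Initial bias of the sigmoid output layer: logit of the prior."""
        p = self.head_bias_prior
        if not 0 < p < 1:
            raise ValueError("head_bias_prior must be in (0, 1)")
        import math

        return math.log(p / (1 - p))


def vnet_filter_plan(cfg: ModelConfig) -> list[int]:
    """Arithmetic filter progression: base, 2*base, 3*base, ... per level."""
    base = cfg.scaled(cfg.base_filters)
    return [base * (i + 1) for i in range(cfg.levels)]


def tl_decoder_filter_plan(cfg: ModelConfig) -> list[int]:
    """Decoder filters for levels P7..P3; (360, 288, 216, 144, 72) at scale 1."""
    plan = [cfg.scaled(f) for f in TL_DECODER_FILTERS]
    return plan[-cfg.levels :] if cfg.levels < len(plan) else plan


def effdet3d_level_channels(cfg: ModelConfig) -> list[int]:
    """Backbone channels for levels P1..Pn; (32,24,48,48,64,80,96) at scale 1."""
    plan = [cfg.scaled(c) for c in EFFDET3D_LEVEL_CHANNELS]
    return plan[: cfg.levels]


def default_config(arch: str) -> ModelConfig:
    """The full-scale reference configuration for each architecture."""
    if arch == "vnet":
        return ModelConfig(arch="vnet", base_filters=48, levels=4, dropout_rate=0.5)
    if arch in ("tl_unet", "gan"):
        return ModelConfig(arch=arch, levels=5, crop_size=224, dropout_rate=0.5,
                           expansion_factor=6.0)
    if arch == "effdet3d":
        return ModelConfig(arch="effdet3d", levels=7, expansion_factor=2.0,
                           fused_channels=48, dropout_rate=0.2)
    raise ValueError(f"unknown architecture {arch!r}")


def desk_config(arch: str, input_shape=(32, 32, 8), seed: int = 0) -> ModelConfig:
    """A configuration small enough for CPU-only forward/backward passes."""
    cfg = default_config(arch)
    cfg.input_shape = tuple(input_shape)
    cfg.seed = seed
    if arch == "vnet":
        cfg.base_filters = 8
        cfg.levels = 2
    elif arch in ("tl_unet", "gan"):
        cfg.levels = 3
        cfg.crop_size = min(24, input_shape[0] - input_shape[0] // 4)
        cfg.crop_size -= cfg.crop_size % (1 << cfg.levels)
        cfg.scale = 0.12
    elif arch == "effdet3d":
        cfg.levels = 3
        cfg.scale = 0.25
        cfg.fused_channels = 12
    return cfg
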