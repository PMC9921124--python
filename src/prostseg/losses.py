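"""Training objectives.

The segmentation networks are trained with a top-k pixel loss that only
counts the k most poorly segmented pixels (k = 5% of the grid, i.e. 143,360
on the clinical 320x320x28 volumes). Because mixup makes the targets soft,
the per-pixel term penalizes the distance from the (possibly non-binary)
target: l = -log(1 - |y - yhat|). With binary targets and k equal to all
pixels this reduces exactly to binary cross-entropy.

The GAN uses relativistic losses on the discriminator score difference and a
soft Dice term on the generator with a 5:1 weight in favour of Dice.

All losses accept either numpy arrays or autograd tensors and return an
autograd scalar, so the same code path serves evaluation and training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossConfig",
    "topk_pixel_count",
    "mixup_topk_loss",
    "soft_dice_loss",
    "relativistic_d_loss",
    "relativistic_g_loss",
    "generator_total_loss",
    "LOSS_REGISTRY",
]


@dataclass
class LossConfig:
    topk_fraction: float = 0.05
    gan_dice_weight: float = 5.0
    gan_adv_weight: float = 1.0
    eps: float = 1e-7

    def __post_init__(self):
        if not 0 < self.topk_fraction <= 1:
            raise ValueError("topk_fraction must be in (0, 1]")
        if self.gan_dice_weight < 0 or self.gan_adv_weight < 0 or self.eps <= 0:
            raise ValueError("weights must be >= 0 and eps > 0")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def topk_pixel_count(shape, fraction: float = 0.05) -> int:
    """round(fraction x number of pixels), clamped to at least 1.

    At the clinical full scale (320, 320, 28) and fraction 0.05 this is
    143,360 pixels.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError(f"non-positive shape {shape}")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return max(1, int(round(fraction * int(np.prod(shape)))))


def mixup_topk_loss(y, yhat, k: int, eps: float = 1e-7) -> Tensor:
    """Mean of the k largest per-pixel terms -log(1 - |y - yhat|).

    |y - yhat| is clipped to 1 - eps so the log stays finite when the
    prediction saturates against a soft target. Ties at the k-th value are
    broken arbitrarily — any choice gives the same mean.
    """
    y, yhat = _as_tensor(y), _as_tensor(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    n = y.size
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    diff = (y - yhat).abs().clip(None, 1.0 - eps)
    pix = -(1.0 - diff).log()
    if k == n:
        return pix.mean()
    idx = np.argpartition(pix.data.reshape(-1), n - k)[n - k :]
    return pix.take_flat(idx).mean()


def soft_dice_loss(y, yhat, smooth: float = 1.0) -> Tensor:
    """1 - (2 sum(y*yhat) + s) / (sum(y) + sum(yhat) + s).

    The smoothing constant ``s`` keeps the ratio defined for empty targets
    and bounds the loss away from the degenerate 0/0 case.
    """
    y, yhat = _as_tensor(y), _as_tensor(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    inter = (y * yhat).sum()
    denom = y.sum() + yhat.sum()
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def _softplus(x: Tensor) -> Tensor:
    # log(1 + exp(x)), stabilized: max(x,0) + log(1 + exp(-|x|))
    return x.relu() + (1.0 + (-x.abs()).exp()).log()


def relativistic_d_loss(d_real, d_fake) -> Tensor:
    """-log(sigmoid(D(x) - D(xhat))), numerically stable for large gaps."""
    d_real, d_fake = _as_tensor(d_real), _as_tensor(d_fake)
    return _softplus(-(d_real - d_fake)).mean()


def relativistic_g_loss(d_real, d_fake) -> Tensor:
    """-log(sigmoid(D(xhat) - D(x))) — the mirror of the discriminator loss."""
    d_real, d_fake = _as_tensor(d_real), _as_tensor(d_fake)
    return _softplus(-(d_fake - d_real)).mean()


def generator_total_loss(y, yhat, d_real, d_fake, cfg: LossConfig | None = None) -> Tensor:
    """Weighted generator objective: 5 x soft Dice + 1 x adversarial."""
    cfg = cfg or LossConfig()
    return (
        cfg.gan_dice_weight * soft_dice_loss(y, yhat)
        + cfg.gan_adv_weight * relativistic_g_loss(d_real, d_fake)
    )


LOSS_REGISTRY = {
    "topk_ce": mixup_topk_loss,
    "dice": soft_dice_loss,
    "rgan": (relativistic_d_loss, relativistic_g_loss),
}
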