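"""Training loops, optimizer schedules, and thresholded inference.

Plain models: Adam (beta1=0.9, beta2=0.999), batch size 2, top-k pixel loss,
learning rate stepped down 0.001 -> 0.0005 -> 0.0001 when the monitored
training loss plateaus. GAN: separate Adam optimizers with beta1=0.5,
beta2=0.999, lr 1e-4 for the generator and 1e-3 for the discriminator,
relativistic losses, and a 5:1 Dice weighting on the generator objective.
Since every generated mask has a corresponding ground truth, real/fake
discriminator scores are computed on paired inputs without sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, TrainingSample, augment_pipeline
from .core import SegMask, VolumeImage
from .losses import (
    LossConfig,
    generator_total_loss,
    mixup_topk_loss,
    relativistic_d_loss,
    soft_dice_loss,
    topk_pixel_count,
)
from .nn import Adam, Layer, Tensor, concat

__all__ = ["TrainConfig", "TrainState", "train_model", "train_gan", "predict_mask"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 2
    lr_schedule: tuple[float, ...] = (1e-3, 5e-4, 1e-4)
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    gan_beta1: float = 0.5
    gan_beta2: float = 0.999
    lr_generator: float = 1e-4
    lr_discriminator: float = 1e-3
    max_steps: int = 300
    patience: int = 10
    min_delta: float = 1e-4
    topk_fraction: float = 0.05
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if any(lr <= 0 for lr in self.lr_schedule) or list(self.lr_schedule) != sorted(
            self.lr_schedule, reverse=True
        ):
            raise ValueError("lr_schedule must be positive and strictly decreasing")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainState:
    step: int = 0
    current_lr: float = 0.0
    lr_stage: int = 0
    loss_history: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    best_loss: float = np.inf
    plateau_counter: int = 0

    def record(self, loss: float, cfg: TrainConfig) -> None:
        self.step += 1
        self.loss_history.append(loss)
        self.lr_history.append(self.current_lr)
        if loss < self.best_loss - cfg.min_delta:
            self.best_loss = loss
            self.plateau_counter = 0
        else:
            self.plateau_counter += 1

    def maybe_anneal(self, cfg: TrainConfig) -> bool:
        if self.plateau_counter >= cfg.patience and self.lr_stage + 1 < len(cfg.lr_schedule):
            self.lr_stage += 1
            self.current_lr = cfg.lr_schedule[self.lr_stage]
            self.plateau_counter = 0
            log.info("step %d: annealing learning rate to %g", self.step, self.current_lr)
            return True
        return False


def _make_batch(
    dataset: list[TrainingSample],
    cfg: TrainConfig,
    rng: np.random.Generator,
    augment_cfg: AugmentConfig | None,
) -> tuple[Tensor, Tensor]:
    n = len(dataset)
    size = min(cfg.batch_size, n)
    idx = rng.choice(n, size=size, replace=n < cfg.batch_size)
    imgs, labs = [], []
    for i in idx:
        s = dataset[i]
        if cfg.augment:
            # mixup partner drawn from the rest of the epoch pool
            if n > 1:
                j = int(rng.integers(n - 1))
                partner = dataset[j + 1 if j >= i else j]
            else:
                partner = s
            s = augment_pipeline(s, partner, rng, augment_cfg)
        imgs.append(s.image.voxels)
        labs.append(s.label.voxels)
    x = Tensor(np.stack(imgs)[:, None])
    y = Tensor(np.stack(labs)[:, None])
    return x, y


def train_model(
    model: Layer,
    dataset: list[TrainingSample],
    cfg: TrainConfig | None = None,
    augment_cfg: AugmentConfig | None = None,
) -> tuple[Layer, TrainState]:
    """Seeded mini-batch training with the top-k pixel loss."""
    cfg = cfg or TrainConfig()
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr_schedule[0],
               beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    state = TrainState(current_lr=cfg.lr_schedule[0])
    shape = dataset[0].image.shape
    k = topk_pixel_count(shape, cfg.topk_fraction)
    for _ in range(cfg.max_steps):
        x, y = _make_batch(dataset, cfg, rng, augment_cfg)
        yhat = model(x, train=True)
        loss = mixup_topk_loss(y, yhat, k=min(k * x.shape[0], y.size))
        val = loss.item()
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite loss {val} at step {state.step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.record(val, cfg)
        if state.maybe_anneal(cfg):
            opt.lr = state.current_lr
    return model, state


def train_gan(
    generator: Layer,
    discriminator: Layer,
    dataset: list[TrainingSample],
    cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    augment_cfg: AugmentConfig | None = None,
) -> tuple[Layer, Layer, TrainState]:
    """Alternating GAN training: one discriminator and one generator update
    per combined step. The 'real' pair presented to the discriminator is the
    ground truth concatenated with itself; the 'fake' pair is ground truth
    with the generated mask."""
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    opt_g = Adam(generator.parameters(), lr=cfg.lr_generator,
                 beta1=cfg.gan_beta1, beta2=cfg.gan_beta2)
    opt_d = Adam(discriminator.parameters(), lr=cfg.lr_discriminator,
                 beta1=cfg.gan_beta1, beta2=cfg.gan_beta2)
    state = TrainState(current_lr=cfg.lr_generator)
    for _ in range(cfg.max_steps):
        x, y = _make_batch(dataset, cfg, rng, augment_cfg)

        # discriminator update on a detached generator output
        yhat = generator(x, train=True).detach()
        d_real = discriminator(concat([y, y], axis=1), train=True)
        d_fake = discriminator(concat([y, Tensor(yhat.data)], axis=1), train=True)
        d_loss = relativistic_d_loss(d_real, d_fake)
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()

        # generator update; discriminator weights are not stepped
        yhat = generator(x, train=True)
        d_real = discriminator(concat([y, y], axis=1), train=True)
        d_fake = discriminator(concat([y, yhat], axis=1), train=True)
        g_loss = generator_total_loss(y, yhat, d_real, d_fake, loss_cfg)
        val = g_loss.item()
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite generator loss at step {state.step}")
        opt_g.zero_grad()
        opt_d.zero_grad()
        g_loss.backward()
        opt_g.step()
        state.record(val, cfg)
    return generator, discriminator, state


def predict_mask(model: Layer, vol: VolumeImage, threshold: float = 0.5) -> SegMask:
    """Forward pass in inference mode, binarized at ``threshold``."""
    x = Tensor(vol.voxels[None, None])
    yhat = model(x, train=False)
    if yhat.shape != x.shape:
        raise ValueError(f"model output shape {yhat.shape} != input {x.shape}")
    prob = yhat.data[0, 0]
    return SegMask((prob > threshold).astype(np.float64), binary=True,
                   spacing=vol.spacing, patient_id=vol.patient_id)


def soft_dice_score(model: Layer, sample: TrainingSample) -> float:
    """Evaluation-mode Dice of the thresholded prediction against the label."""
    pred = predict_mask(model, sample.image)
    inter = (pred.voxels * sample.label.voxels).sum()
    denom = pred.voxels.sum() + sample.label.voxels.sum()
    return float(2 * inter / denom) if denom else 1.0
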