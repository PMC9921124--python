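"""Synthetic prostate-like MRI phantoms.

The study's clinical cohort (100 T2-weighted scans with expert contours) is
private, so this module generates stand-in cohorts with the same statistical
structure: a roughly ellipsoidal organ of variable volume on an anisotropic
grid, a smooth multiplicative bias field, additive noise, and per-patient
clinical covariates (age, prostate volume, iPSA, ISUP, ECE, PIRADS). The
phantoms exercise every downstream module; they make no claim of anatomical
realism (no zonal anatomy, no lesions, no Rician noise floor by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import SegMask, VolumeImage

__all__ = [
    "PhantomConfig",
    "CovariateModel",
    "ClinicalCovariates",
    "PhantomSample",
    "generate_phantom",
    "generate_cohort",
    "degrade_mask",
    "inflate_to_ratio",
]


@dataclass
class PhantomConfig:
    """Geometry and corruption settings for one synthetic scan.

    Defaults are desk-scale (64x64x16); the clinical grid the study used is
    320x320x28 at 0.59x0.59x~3.3 mm. ``radii_range_mm`` spans adult prostate
    semi-axes (roughly 25-90 ml organs at the defaults).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.2, 1.2, 3.3)
    radii_range_mm: tuple[float, float] = (14.0, 24.0)
    contrast: float = 2.0  # foreground / background intensity ratio
    noise_sd: float = 0.05
    bias_amplitude: float = 0.2
    boundary_perturbation: float = 0.0  # relative level-set wobble
    rician: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd and bias_amplitude must be >= 0")
        lo, hi = self.radii_range_mm
        if not 0 < lo <= hi:
            raise ValueError("radii range must be positive and ordered")
        half_fov = [0.5 * n * s for n, s in zip(self.grid_shape, self.spacing)]
        if hi >= min(half_fov):
            raise ValueError(
                f"max radius {hi} mm does not fit inside half the field of view {half_fov}"
            )


@dataclass
class ClinicalCovariates:
    """Per-patient clinical variables mirroring the study's covariate panel."""

    age: float
    prostate_volume_ml: float
    ipsa: float
    isup: int
    ece: int
    pirads: int

    def __post_init__(self):
        if self.age <= 0 or self.prostate_volume_ml <= 0 or self.ipsa <= 0:
            raise ValueError("continuous covariates must be positive")
        if self.isup not in range(1, 6):
            raise ValueError("ISUP grade must be 1-5")
        if self.ece not in range(0, 4):
            raise ValueError("ECE score must be 0-3")
        if self.pirads not in range(2, 6):
            raise ValueError("PIRADS category must be 2-5")


@dataclass
class CovariateModel:
    """Sampling distributions for the clinical covariates.

    age ~ Normal(70, 7) years; iPSA ~ LogNormal (median ~8 ng/ml); the
    ordinal variables are categorical with the given probabilities. Prostate
    volume is not sampled here — it is read off the generated mask.
    """

    age_mean: float = 70.0
    age_sd: float = 7.0
    ipsa_log_mean: float = np.log(8.0)
    ipsa_log_sd: float = 0.6
    isup_probs: tuple[float, ...] = (0.15, 0.30, 0.25, 0.18, 0.12)  # grades 1-5
    ece_probs: tuple[float, ...] = (0.55, 0.05, 0.25, 0.15)  # scores 0-3
    pirads_probs: tuple[float, ...] = (0.05, 0.20, 0.45, 0.30)  # categories 2-5

    def sample(self, volume_ml: float, rng: np.random.Generator) -> ClinicalCovariates:
        return ClinicalCovariates(
            age=float(np.clip(rng.normal(self.age_mean, self.age_sd), 40.0, 95.0)),
            prostate_volume_ml=volume_ml,
            ipsa=float(np.exp(rng.normal(self.ipsa_log_mean, self.ipsa_log_sd))),
            isup=int(rng.choice(np.arange(1, 6), p=_norm(self.isup_probs))),
            ece=int(rng.choice(np.arange(0, 4), p=_norm(self.ece_probs))),
            pirads=int(rng.choice(np.arange(2, 6), p=_norm(self.pirads_probs))),
        )


def _norm(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return p / p.sum()


@dataclass
class PhantomSample:
    image: VolumeImage
    mask: SegMask
    true_volume_ml: float
    covariates: ClinicalCovariates | None = None


def _physical_coords(shape, spacing):
    """Centered physical coordinates (mm) for each axis."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]


def ellipsoid_mask(
    shape, spacing, radii_mm, angle: float = 0.0, perturbation: np.ndarray | None = None
) -> np.ndarray:
    """Voxelize an (optionally rotated, level-set-perturbed) ellipsoid."""
    ys, xs, zs = _physical_coords(shape, spacing)
    Y, X, Z = np.meshgrid(ys, xs, zs, indexing="ij")
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        Y, X = c * Y - s * X, s * Y + c * X
    a, b, c3 = radii_mm
    q = (Y / a) ** 2 + (X / b) ** 2 + (Z / c3) ** 2
    if perturbation is not None:
        q = q + perturbation
    return q <= 1.0


def _smooth_field(shape, rng: np.random.Generator, order: int = 2) -> np.ndarray:
    """Zero-mean sum of low-order separable cosine modes, unit max-amplitude."""
    axes = [np.linspace(0.0, np.pi, n) for n in shape]
    out = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1):
            for k in range(order + 1):
                if i + j + k == 0 or i + j + k > order:
                    continue
                coef = rng.normal()
                out += coef * np.multiply.outer(
                    np.multiply.outer(np.cos(i * axes[0]), np.cos(j * axes[1])),
                    np.cos(k * axes[2]),
                )
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


def generate_phantom(
    cfg: PhantomConfig, rng: np.random.Generator | None = None, patient_id: str = "P000"
) -> PhantomSample:
    """One synthetic scan: mask, intensity volume, and its true volume in ml.

    image = (background 1.0 / foreground ``contrast``) x exp(bias) + noise.
    Deterministic given ``cfg.seed`` (or an injected generator).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.radii_range_mm
    radii = rng.uniform(lo, hi, size=3)
    angle = rng.uniform(-np.pi / 4, np.pi / 4)
    perturbation = None
    if cfg.boundary_perturbation > 0:
        perturbation = cfg.boundary_perturbation * _smooth_field(cfg.grid_shape, rng, order=3)
    mask = ellipsoid_mask(cfg.grid_shape, cfg.spacing, radii, angle, perturbation)
    if not mask.any():
        raise ValueError("degenerate phantom: empty mask")

    base = np.where(mask, cfg.contrast, 1.0)
    if cfg.bias_amplitude > 0:
        bias = np.exp(cfg.bias_amplitude * _smooth_field(cfg.grid_shape, rng, order=2))
    else:
        bias = 1.0
    image = base * bias
    if cfg.noise_sd > 0:
        if cfg.rician:
            re = image + rng.normal(0.0, cfg.noise_sd, cfg.grid_shape)
            im = rng.normal(0.0, cfg.noise_sd, cfg.grid_shape)
            image = np.sqrt(re**2 + im**2)
        else:
            image = image + rng.normal(0.0, cfg.noise_sd, cfg.grid_shape)

    seg = SegMask(mask.astype(np.float64), binary=True, spacing=cfg.spacing, patient_id=patient_id)
    vol = VolumeImage(image, spacing=cfg.spacing, patient_id=patient_id)
    return PhantomSample(image=vol, mask=seg, true_volume_ml=seg.volume_ml)


def generate_cohort(
    n: int,
    cfg: PhantomConfig,
    covariate_model: CovariateModel | None = None,
    rng: np.random.Generator | None = None,
) -> list[PhantomSample]:
    """A cohort of ``n`` phantoms with distinct ids and sampled covariates."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    model = covariate_model if covariate_model is not None else CovariateModel()
    samples = []
    for i in range(n):
        sample = generate_phantom(cfg, rng, patient_id=f"P{i:03d}")
        sample.covariates = model.sample(sample.true_volume_ml, rng)
        samples.append(sample)
    return samples


def inflate_to_ratio(mask: SegMask, ratio: float) -> SegMask:
    """Grow or shrink a binary mask to exactly round(ratio x voxel count).

    Voxels are added (removed) in order of Euclidean distance to the current
    boundary, ties broken by flat index, so the result is deterministic and
    morphologically uniform — e.g. ratio 1.3 yields a prediction whose ARVD
    against the original is exactly 0.3 (up to the rounding of the count).
    """
    m = mask.as_bool()
    count = int(m.sum())
    if count == 0:
        raise ValueError("cannot inflate an empty mask")
    target = int(round(count * ratio))
    out = m.copy()
    if target > count:
        dist = ndimage.distance_transform_edt(~m)
        candidates = np.flatnonzero(~m.ravel())
        order = np.lexsort((candidates, dist.ravel()[candidates]))
        out.ravel()[candidates[order[: target - count]]] = True
    elif target < count:
        if target <= 0:
            raise ValueError("ratio would empty the mask")
        dist = ndimage.distance_transform_edt(m)
        candidates = np.flatnonzero(m.ravel())
        order = np.lexsort((candidates, dist.ravel()[candidates]))
        out.ravel()[candidates[order[: count - target]]] = False
    return SegMask(out.astype(np.float64), binary=True, spacing=mask.spacing,
                   patient_id=mask.patient_id)


def degrade_mask(
    mask: SegMask,
    mode: str,
    magnitude,
    rng: np.random.Generator | None = None,
    allow_empty: bool = False,
) -> SegMask:
    """Controlled perturbations of a binary mask for metric testing.

    Modes: ``dilate`` / ``erode`` by ``magnitude`` morphological iterations
    (3D, 6-connectivity), ``shift`` by ``magnitude`` = (rows, cols) pixels
    in-plane with zero fill, ``dropslices`` zeroing ``magnitude`` randomly
    chosen nonempty slices.
    """
    m = mask.as_bool()
    struct = ndimage.generate_binary_structure(3, 1)
    if mode == "dilate":
        out = ndimage.binary_dilation(m, struct, iterations=int(magnitude)) if magnitude else m
    elif mode == "erode":
        out = ndimage.binary_erosion(m, struct, iterations=int(magnitude)) if magnitude else m
        if not out.any() and not allow_empty:
            raise ValueError("erosion emptied the mask")
    elif mode == "shift":
        dr, dc = (int(magnitude), 0) if np.isscalar(magnitude) else map(int, magnitude)
        out = np.zeros_like(m)
        src_r = slice(max(0, -dr), m.shape[0] - max(0, dr))
        dst_r = slice(max(0, dr), m.shape[0] - max(0, -dr))
        src_c = slice(max(0, -dc), m.shape[1] - max(0, dc))
        dst_c = slice(max(0, dc), m.shape[1] - max(0, -dc))
        out[dst_r, dst_c, :] = m[src_r, src_c, :]
    elif mode == "dropslices":
        k = int(magnitude)
        out = m.copy()
        if k:
            if rng is None:
                raise ValueError("dropslices requires an rng")
            nonempty = np.flatnonzero(m.any(axis=(0, 1)))
            drop = rng.choice(nonempty, size=min(k, len(nonempty)), replace=False)
            out[:, :, drop] = False
    else:
        raise ValueError(f"unknown degradation mode {mode!r}")
    if not out.any() and not allow_empty:
        raise ValueError(f"degradation {mode!r} emptied the mask")
    return SegMask(out.astype(np.float64), binary=True, spacing=mask.spacing,
                   patient_id=mask.patient_id)
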