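"""Training-time augmentation chain.

Applied in this order: mixup, horizontal flips (p=0.5), uniform random
rotation in [-pi/4, pi/4] about the depth axis, random bilinear resize and
translation with scale in [0.7, 1.3], and a fast elastic deformation built
from blurred low-resolution noise. Geometric transforms act identically on
image and label; labels are interpolated bilinearly and left soft (they are
already soft after mixup), so label values never leave [0, 1].

Every operation takes an injected ``numpy.random.Generator`` and exposes its
random draw as an overridable keyword (``lam``, ``flip``, ``angle`` ...) so
tests can force exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import SegMask, VolumeImage

__all__ = [
    "TrainingSample",
    "ElasticConfig",
    "DeformationField",
    "AugmentConfig",
    "mixup",
    "random_hflip",
    "random_rotate",
    "random_scale_translate",
    "elastic_field",
    "apply_field",
    "augment_pipeline",
]


@dataclass
class TrainingSample:
    """One (image, label) pair ready for the networks.

    The label may be soft (values in [0, 1]) after mixup or interpolation.
    """

    image: VolumeImage
    label: SegMask

    def __post_init__(self):
        if self.image.shape != self.label.shape:
            raise ValueError(
                f"image/label shape mismatch: {self.image.shape} vs {self.label.shape}"
            )

    def replace_arrays(self, img: np.ndarray, lab: np.ndarray) -> "TrainingSample":
        lab = np.clip(lab, 0.0, 1.0)
        return TrainingSample(
            image=self.image.with_voxels(img),
            label=SegMask(lab, binary=False, spacing=self.label.spacing,
                          patient_id=self.label.patient_id),
        )


@dataclass
class ElasticConfig:
    """Parameters of the fast elastic deformation.

    ``alpha`` scales the displacement amplitude (pixels), ``beta`` is the
    down-scaling factor the noise is generated at (a pure speed-up), and
    ``sigma`` is the Gaussian blur standard deviation in down-scaled pixels.
    """

    alpha: float = 2000.0
    beta: float = 0.25
    sigma: float = 50.0

    def __post_init__(self):
        if self.alpha < 0 or not (0 < self.beta <= 1) or self.sigma <= 0:
            raise ValueError(f"invalid elastic config {self}")

    @classmethod
    def for_shape(cls, in_plane_shape: tuple[int, int]) -> "ElasticConfig":
        """Defaults rescaled to a grid other than the clinical 320x320.

        The blur width shrinks linearly with the grid (sigma ~ s) and the
        amplitude quadratically (alpha ~ s^2), which keeps the displacement
        a constant fraction of the field of view.
        """
        s = min(in_plane_shape) / 320.0
        if s >= 1.0:
            return cls()
        return cls(alpha=2000.0 * s * s, beta=0.25, sigma=max(3.0, 50.0 * s))


@dataclass
class DeformationField:
    """Per-pixel 2D remap shared by all slices.

    Semantics (as in ``cv2.remap``): output(r, c) = input(map_y(r, c),
    map_x(r, c)) — ``map_x`` holds column coordinates, ``map_y`` rows.
    """

    map_x: np.ndarray
    map_y: np.ndarray

    def __post_init__(self):
        if self.map_x.shape != self.map_y.shape or self.map_x.ndim != 2:
            raise ValueError("map_x and map_y must be equal-shaped 2D grids")

    @property
    def shape(self):
        return self.map_x.shape

    def displacement(self) -> tuple[np.ndarray, np.ndarray]:
        H, W = self.shape
        yy, xx = np.mgrid[0:H, 0:W]
        return self.map_x - xx, self.map_y - yy


@dataclass
class AugmentConfig:
    mixup_alpha: float = 0.5
    hflip_prob: float = 0.5
    rotate_range: float = np.pi / 4
    scale_range: tuple[float, float] = (0.7, 1.3)
    translate_frac: float = 0.1  # of the in-plane extent; protocol left it open
    elastic: ElasticConfig | None = None  # None: defaults rescaled to the grid


# ---------------------------------------------------------------------------


def mixup(
    s1: TrainingSample,
    s2: TrainingSample,
    alpha: float = 0.5,
    rng: np.random.Generator | None = None,
    lam: float | None = None,
) -> TrainingSample:
    """Convex combination of two samples with lambda ~ Beta(alpha, alpha)."""
    if s1.image.shape != s2.image.shape:
        raise ValueError("mixup requires equal-shaped samples")
    if lam is None:
        if alpha <= 0:
            raise ValueError("mixup alpha must be positive")
        if rng is None:
            raise ValueError("mixup requires an rng when lam is not forced")
        lam = float(rng.beta(alpha, alpha))
    img = lam * s1.image.voxels + (1 - lam) * s2.image.voxels
    lab = lam * s1.label.voxels + (1 - lam) * s2.label.voxels
    return s1.replace_arrays(img, lab)


def random_hflip(
    s: TrainingSample, rng: np.random.Generator | None = None, flip: bool | None = None
) -> TrainingSample:
    """Reverse the column axis of image and label jointly with p = 0.5."""
    if flip is None:
        flip = bool(rng.random() < 0.5)
    if not flip:
        return s
    return s.replace_arrays(s.image.voxels[:, ::-1, :].copy(), s.label.voxels[:, ::-1, :].copy())


def random_rotate(
    s: TrainingSample,
    rng: np.random.Generator | None = None,
    angle: float | None = None,
    max_angle: float = np.pi / 4,
) -> TrainingSample:
    """One in-plane rotation angle applied to every slice; zero fill."""
    if angle is None:
        angle = float(rng.uniform(-max_angle, max_angle))
    if angle == 0.0:
        return s
    deg = np.degrees(angle)
    img = ndimage.rotate(s.image.voxels, deg, axes=(0, 1), reshape=False, order=1,
                         mode="constant", cval=0.0)
    lab = ndimage.rotate(s.label.voxels, deg, axes=(0, 1), reshape=False, order=1,
                         mode="constant", cval=0.0)
    return s.replace_arrays(img, lab)


def random_scale_translate(
    s: TrainingSample,
    rng: np.random.Generator | None = None,
    scale: float | None = None,
    translation: tuple[float, float] | None = None,
    scale_range: tuple[float, float] = (0.7, 1.3),
    translate_frac: float = 0.1,
) -> TrainingSample:
    """In-plane scaling about the image centre plus a bounded translation.

    Bilinear, output shape preserved (content is implicitly cropped or
    zero-padded by the resample).
    """
    H, W, _ = s.image.shape
    if scale is None:
        scale = float(rng.uniform(*scale_range))
    if translation is None:
        ty = float(rng.uniform(-translate_frac, translate_frac) * H)
        tx = float(rng.uniform(-translate_frac, translate_frac) * W)
        translation = (ty, tx)
    if scale == 1.0 and translation == (0.0, 0.0):
        return s
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    matrix = np.diag([1.0 / scale, 1.0 / scale, 1.0])
    center = np.array([cy, cx, 0.0])
    shift = np.array([translation[0], translation[1], 0.0])
    offset = center - matrix @ (center + shift)
    img = ndimage.affine_transform(s.image.voxels, matrix, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    lab = ndimage.affine_transform(s.label.voxels, matrix, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    return s.replace_arrays(img, lab)


def elastic_field(
    in_plane_shape: tuple[int, int],
    cfg: ElasticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DeformationField:
    """Build the fast elastic deformation maps.

    Two uniform [-1, 1] noise matrices at the resolution down-scaled by
    ``beta`` are Gaussian-blurred (std ``sigma``, reflective boundaries),
    scaled by ``alpha``, bilinearly rescaled to full resolution, and added to
    the identity mesh grids.
    """
    cfg = cfg or ElasticConfig()
    H, W = in_plane_shape
    h, w = max(int(round(H * cfg.beta)), 1), max(int(round(W * cfg.beta)), 1)
    if h < 3 or w < 3:
        raise ValueError(f"down-scaled shape {(h, w)} too small; need >= 3 per axis")
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    if cfg.alpha == 0:
        return DeformationField(map_x=xx, map_y=yy)
    if rng is None:
        raise ValueError("elastic_field requires an rng when alpha > 0")
    dx = rng.uniform(-1.0, 1.0, size=(h, w))
    dy = rng.uniform(-1.0, 1.0, size=(h, w))
    dx = ndimage.gaussian_filter(dx, cfg.sigma, mode="reflect") * cfg.alpha
    dy = ndimage.gaussian_filter(dy, cfg.sigma, mode="reflect") * cfg.alpha
    zoom = (H / h, W / w)
    dx = ndimage.zoom(dx, zoom, order=1, mode="nearest", grid_mode=True)
    dy = ndimage.zoom(dy, zoom, order=1, mode="nearest", grid_mode=True)
    return DeformationField(map_x=xx + dx[:H, :W], map_y=yy + dy[:H, :W])


def apply_field(s: TrainingSample, field: DeformationField) -> TrainingSample:
    """Remap every slice of image and label through the deformation maps."""
    H, W, D = s.image.shape
    if field.shape != (H, W):
        raise ValueError(f"field shape {field.shape} != in-plane shape {(H, W)}")
    coords = np.stack([field.map_y, field.map_x])
    img = np.empty_like(s.image.voxels)
    lab = np.empty_like(s.label.voxels)
    for k in range(D):
        img[:, :, k] = ndimage.map_coordinates(s.image.voxels[:, :, k], coords, order=1,
                                               mode="constant", cval=0.0)
        lab[:, :, k] = ndimage.map_coordinates(s.label.voxels[:, :, k], coords, order=1,
                                               mode="constant", cval=0.0)
    return s.replace_arrays(img, lab)


def augment_pipeline(
    s1: TrainingSample,
    s2: TrainingSample,
    rng: np.random.Generator,
    cfg: AugmentConfig | None = None,
) -> TrainingSample:
    """The full chain in order: mixup, flip, rotate, resize/translate, elastic."""
    cfg = cfg or AugmentConfig()
    s = mixup(s1, s2, alpha=cfg.mixup_alpha, rng=rng)
    s = random_hflip(s, rng)
    s = random_rotate(s, rng, max_angle=cfg.rotate_range)
    s = random_scale_translate(s, rng, scale_range=cfg.scale_range,
                               translate_frac=cfg.translate_frac)
    ecfg = cfg.elastic if cfg.elastic is not None else ElasticConfig.for_shape(s.image.shape[:2])
    field = elastic_field(s.image.shape[:2], ecfg, rng)
    return apply_field(s, field)
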