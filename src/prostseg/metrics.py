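"""Segmentation evaluation scores: Dice, ARVD, and slice-wise MSD / HD95.

Manual prostate contours are drawn slice by slice on grids with strongly
anisotropic voxels (0.59 mm in-plane vs ~3.3 mm between slices), so the two
surface-distance scores are computed in 2D within each axial slice, in pixel
units. A slice where exactly one mask has no contour contributes via the
convention that the empty contour is a single pixel at the image centre;
slices where both masks are empty are skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import SegMask

__all__ = [
    "dice",
    "arvd",
    "extract_surface_2d",
    "msd_2d",
    "hd95_2d",
    "score_patient",
    "ScoreRecord",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class ScoreRecord:
    """Per-patient quadruple of segmentation scores.

    Units: ``dice`` unitless in [0, 1]; ``arvd`` a nonnegative fraction;
    ``msd`` and ``hd95`` in pixels.
    """

    patient_id: str
    dice: float
    arvd: float
    msd: float
    hd95: float

    def __post_init__(self):
        if not 0 <= self.dice <= 1:
            raise ValueError(f"dice out of [0,1]: {self.dice}")
        if self.arvd < 0 or self.msd < 0 or self.hd95 < 0:
            raise ValueError("arvd/msd/hd95 must be nonnegative")


def _as_bool(mask: SegMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, SegMask):
        if not mask.binary:
            raise ValueError("metrics require binary masks")
        return mask.as_bool()
    arr = np.asarray(mask)
    if not np.all(np.isin(arr, (0, 1, True, False))):
        raise ValueError("metrics require binary masks")
    return arr.astype(bool)


def _check_pair(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_bool(pred), _as_bool(gt)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice(pred: SegMask | np.ndarray, gt: SegMask | np.ndarray) -> float:
    """Dice overlap coefficient 2|A∩B| / (|A|+|B|)."""
    a, b = _check_pair(pred, gt)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Dice is undefined for two empty masks")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def arvd(pred: SegMask | np.ndarray, gt: SegMask | np.ndarray) -> float:
    """Absolute relative volume difference |V_pred − V_gt| / V_gt.

    The denominator is the ground-truth volume, so the score is *not*
    symmetric. On a shared grid the voxel-count ratio equals the
    physical-volume ratio.
    """
    a, b = _check_pair(pred, gt)
    vb = b.sum()
    if vb == 0:
        raise ValueError("ARVD is undefined for an empty ground truth")
    return float(abs(int(a.sum()) - int(vb)) / vb)


def extract_surface_2d(mask_slice: np.ndarray) -> np.ndarray:
    """Boundary pixels of a 2D binary slice as an (n, 2) array of (row, col).

    A foreground pixel is on the surface if any 4-connected neighbour is
    background or if it touches the image border. Empty slices give an
    empty (0, 2) array.
    """
    m = np.asarray(mask_slice).astype(bool)
    if m.ndim != 2:
        raise ValueError("expected a 2D slice")
    if not m.any():
        return np.empty((0, 2), dtype=np.int64)
    interior = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    return np.argwhere(m & ~interior)


def _center_pixel(shape: tuple[int, int]) -> np.ndarray:
    return np.array([[shape[0] // 2, shape[1] // 2]], dtype=np.int64)


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Euclidean distance from each pixel of ``src`` to the nearest of ``dst``."""
    if len(dst) == 0:
        raise ValueError("destination surface is empty")
    if len(dst) > 16:
        d, _ = cKDTree(dst).query(src)
        return np.asarray(d, dtype=np.float64).reshape(-1)
    diff = src[:, None, :].astype(np.float64) - dst[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def _slice_surfaces(a: np.ndarray, b: np.ndarray):
    """Yield per-slice surface pairs with the empty-contour convention."""
    H, W, D = a.shape
    for s in range(D):
        sa = extract_surface_2d(a[:, :, s])
        sb = extract_surface_2d(b[:, :, s])
        if len(sa) == 0 and len(sb) == 0:
            continue  # both empty: no anatomy to compare in this slice
        if len(sa) == 0:
            sa = _center_pixel((H, W))
        if len(sb) == 0:
            sb = _center_pixel((H, W))
        yield sa, sb


def msd_2d(pred: SegMask | np.ndarray, gt: SegMask | np.ndarray) -> float:
    """Mean surface distance in pixels, pooled over contributing slices.

    The sums of the directed nearest-surface distances (both directions) and
    the surface pixel counts are accumulated over all slices where at least
    one mask is nonempty, then divided once.
    """
    a, b = _check_pair(pred, gt)
    total, count = 0.0, 0
    for sa, sb in _slice_surfaces(a, b):
        total += _directed_distances(sa, sb).sum()
        total += _directed_distances(sb, sa).sum()
        count += len(sa) + len(sb)
    if count == 0:
        raise ValueError("MSD is undefined: both masks are empty everywhere")
    return float(total / count)


def hd95_2d(
    pred: SegMask | np.ndarray,
    gt: SegMask | np.ndarray,
    percentile: float = 95.0,
) -> float:
    """95th-percentile Hausdorff distance in pixels, averaged over slices.

    Per contributing slice the directed distance sets are reduced to their
    95th percentiles (linear interpolation between order statistics) and the
    maximum of the two directions is taken; slice values are then averaged
    without weighting.
    """
    a, b = _check_pair(pred, gt)
    values = []
    for sa, sb in _slice_surfaces(a, b):
        fwd = np.percentile(_directed_distances(sa, sb), percentile)
        bwd = np.percentile(_directed_distances(sb, sa), percentile)
        values.append(max(fwd, bwd))
    if not values:
        raise ValueError("HD95 is undefined: both masks are empty everywhere")
    return float(np.mean(values))


def score_patient(pred: SegMask, gt: SegMask, patient_id: str = "") -> ScoreRecord:
    """Bundle the four scores for one patient."""
    return ScoreRecord(
        patient_id=patient_id or getattr(gt, "patient_id", ""),
        dice=dice(pred, gt),
        arvd=arvd(pred, gt),
        msd=msd_2d(pred, gt),
        hd95=hd95_2d(pred, gt),
    )
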