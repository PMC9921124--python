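"""Reading, resampling, and intensity normalization of MRI volumes.

The pipeline mirrors the study protocol: resample every scan to a common
320x320x28 grid (bilinear in-plane, zero-padded slices when the stack is
short), optionally correct the smooth scanner bias field (N4 via an injected
corrector), clip intensities to the [0th, 98th] percentile interval and map
them affinely onto [0, 4033], and — for the neural models only — z-normalize
each volume to zero mean and unit variance. Train/test splits are checked
for covariate balance with the Mann-Whitney U-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage, stats

from .core import SegMask, VolumeImage

__all__ = [
    "PreprocessConfig",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "clip_and_standardize",
    "znormalize",
    "n4_correct",
    "sitk_n4_corrector",
    "preprocess_volume",
    "make_split",
    "check_split_balance",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    target_shape: tuple[int, int, int] = (320, 320, 28)
    clip_percentiles: tuple[float, float] = (0.0, 98.0)
    standardize_range: tuple[float, float] = (0.0, 4033.0)
    apply_n4: bool = False
    znorm: bool = True

    def __post_init__(self):
        lo, hi = self.clip_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError(f"bad clip percentiles {self.clip_percentiles}")
        if self.standardize_range[1] <= self.standardize_range[0]:
            raise ValueError("standardize upper bound must exceed lower bound")


# ---------------------------------------------------------------------------
# I/O


def read_volume(path: str | Path, format: str = "nifti") -> VolumeImage:
    """Read a volume from a NIfTI file or a DICOM series directory.

    Intensities are returned unchanged; spacing comes from the header. A
    DICOM series with inconsistent slice spacing raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D NIfTI, got shape {data.shape}")
        zooms = img.header.get_zooms()[:3]
        return VolumeImage(data, spacing=tuple(float(z) for z in zooms),
                           patient_id=path.stem.replace(".nii", ""))
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _read_dicom_series(directory: Path) -> VolumeImage:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in {".dcm", ""})
    if not files:
        raise ValueError(f"no DICOM files in {directory}")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception as exc:  # pragma: no cover - corrupt input path
            raise ValueError(f"unreadable DICOM file {f}: {exc}") from exc
    try:
        slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
        zpos = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    except AttributeError:
        slices.sort(key=lambda s: int(s.InstanceNumber))
        zpos = np.arange(len(slices), dtype=float)
    gaps = np.diff(zpos)
    if len(gaps) and (gaps.max() - gaps.min()) > 0.25 * abs(np.median(gaps)):
        raise ValueError(
            f"inconsistent DICOM slice spacing in {directory}: gaps {gaps.round(3)}"
        )
    pixel = np.stack([s.pixel_array.astype(np.float64) for s in slices], axis=-1)
    first = slices[0]
    ps = [float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0])]
    dz = float(abs(np.median(gaps))) if len(gaps) else float(
        getattr(first, "SliceThickness", 1.0)
    )
    pid = str(getattr(first, "PatientID", directory.name))
    return VolumeImage(pixel, spacing=(ps[0], ps[1], dz), patient_id=pid)


def write_volume(vol: VolumeImage | SegMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI with spacing in the affine."""
    import nibabel as nib

    affine = np.diag([*vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64), affine), str(path))


# ---------------------------------------------------------------------------
# Geometry


def resample_to_grid(
    vol: VolumeImage,
    mask: SegMask | None = None,
    target_shape: tuple[int, int, int] = (320, 320, 28),
) -> tuple[VolumeImage, SegMask | None]:
    """Resample onto the common grid.

    In-plane sizes are bilinearly interpolated to the target; a slice deficit
    is filled by appending zero slices, a slice excess is center-cropped (the
    protocol only prescribes padding; cropping mirrors it symmetrically and
    is logged). Masks follow the same geometry and are re-binarized at 0.5.
    """
    th, tw, td = target_shape
    out_img, new_spacing = _resample_array(vol.voxels, vol.spacing, (th, tw, td), order=1)
    out_mask = None
    if mask is not None:
        if mask.shape != vol.shape:
            raise ValueError("mask and volume shapes differ")
        m, _ = _resample_array(mask.voxels, mask.spacing, (th, tw, td), order=1)
        out_mask = SegMask((m > 0.5).astype(np.float64), binary=True,
                           spacing=new_spacing, patient_id=mask.patient_id)
    return (
        VolumeImage(out_img, spacing=new_spacing, patient_id=vol.patient_id, meta=dict(vol.meta)),
        out_mask,
    )


def _resample_array(arr, spacing, target, order):
    H, W, D = arr.shape
    th, tw, td = target
    out = arr
    sy, sx, sz = spacing
    if (H, W) != (th, tw):
        zoom = (th / H, tw / W, 1.0)
        out = ndimage.zoom(out, zoom, order=order, mode="nearest", grid_mode=True)
        sy, sx = sy * H / th, sx * W / tw
    D = out.shape[2]
    if D < td:
        out = np.concatenate([out, np.zeros((th, tw, td - D))], axis=2)
    elif D > td:
        start = (D - td) // 2
        log.info("depth excess: center-cropping %d slices to %d", D, td)
        out = out[:, :, start : start + td]
    return np.ascontiguousarray(out, dtype=np.float64), (sy, sx, sz)


# ---------------------------------------------------------------------------
# Intensities


def clip_and_standardize(vol: VolumeImage, cfg: PreprocessConfig | None = None) -> VolumeImage:
    """Clip to the configured percentile interval and map affinely to range.

    Percentiles use linear interpolation (numpy default). A constant volume
    degenerates to all zeros with a warning rather than an error.
    """
    cfg = cfg or PreprocessConfig()
    lo_p, hi_p = cfg.clip_percentiles
    lo_v, hi_v = np.percentile(vol.voxels, [lo_p, hi_p])
    if hi_v <= lo_v:
        warnings.warn(
            f"constant volume {vol.patient_id!r}: standardization degenerates to zeros",
            stacklevel=2,
        )
        return vol.with_voxels(np.zeros_like(vol.voxels))
    clipped = np.clip(vol.voxels, lo_v, hi_v)
    a, b = cfg.standardize_range
    return vol.with_voxels((clipped - lo_v) / (hi_v - lo_v) * (b - a) + a)


def znormalize(vol: VolumeImage) -> VolumeImage:
    """Normalize to zero mean and unit variance over the whole grid."""
    sd = vol.voxels.std()
    if sd == 0:
        raise ValueError(f"zero-variance volume {vol.patient_id!r} cannot be z-normalized")
    return vol.with_voxels((vol.voxels - vol.voxels.mean()) / sd)


# ---------------------------------------------------------------------------
# Bias-field correction hook

Corrector = Callable[[np.ndarray, tuple[float, float, float]], np.ndarray]


def n4_correct(vol: VolumeImage, corrector: Corrector | None = None) -> VolumeImage:
    """Apply an injected bias-field corrector (e.g. N4); identity if absent.

    The corrector receives ``(voxels, spacing)`` and must return a grid of
    the same shape.
    """
    if corrector is None:
        log.info("no bias-field corrector registered; skipping N4 step")
        return vol
    corrected = np.asarray(corrector(vol.voxels, vol.spacing), dtype=np.float64)
    if corrected.shape != vol.shape:
        raise ValueError(
            f"corrector changed the grid shape: {vol.shape} -> {corrected.shape}"
        )
    return vol.with_voxels(corrected)


def sitk_n4_corrector(**kwargs) -> Corrector:
    """A corrector backed by SimpleITK's N4 implementation (default params)."""
    import SimpleITK as sitk

    def correct(voxels: np.ndarray, spacing) -> np.ndarray:
        img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.T, dtype=np.float32))
        img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
        out = sitk.N4BiasFieldCorrection(img, **kwargs)
        return sitk.GetArrayFromImage(out).T.astype(np.float64)

    return correct


def preprocess_volume(
    vol: VolumeImage,
    mask: SegMask | None = None,
    cfg: PreprocessConfig | None = None,
    corrector: Corrector | None = None,
) -> tuple[VolumeImage, SegMask | None]:
    """Full deterministic pipeline: resample -> N4 -> clip/standardize -> z-norm."""
    cfg = cfg or PreprocessConfig()
    vol, mask = resample_to_grid(vol, mask, cfg.target_shape)
    if cfg.apply_n4:
        vol = n4_correct(vol, corrector)
    vol = clip_and_standardize(vol, cfg)
    if cfg.znorm:
        vol = znormalize(vol)
    return vol, mask


# ---------------------------------------------------------------------------
# Splits


def make_split(patient_ids, ratio: float, seed: int) -> tuple[list, list]:
    """Random disjoint train/test partition with |train| = round(ratio * n)."""
    ids = list(patient_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def check_split_balance(values_train, values_test) -> float:
    """Two-sided Mann-Whitney U p-value for a covariate across the split."""
    a = np.asarray(values_train, dtype=float)
    b = np.asarray(values_test, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both split groups must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
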