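"""Core in-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VolumeImage", "SegMask"]


@dataclass
class VolumeImage:
    """A 3D intensity grid with voxel spacing and provenance metadata.

    ``voxels`` is an ``(H, W, D)`` float array — rows, columns, slices.
    ``spacing`` is the physical voxel size in millimetres per axis.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.59, 0.59, 3.3)
    patient_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.voxels.shape}")
        if min(self.voxels.shape) < 1:
            raise ValueError("every axis must have at least one voxel")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError(f"non-finite voxel values in volume {self.patient_id!r}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        return replace(self, voxels=voxels)


@dataclass
class SegMask:
    """A segmentation mask on the same grid as its paired :class:`VolumeImage`.

    Binary for ground truth and thresholded predictions; soft values in
    [0, 1] after mixup or before thresholding.
    """

    voxels: np.ndarray
    binary: bool = True
    spacing: tuple[float, float, float] = (0.59, 0.59, 3.3)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.voxels.shape}")
        if self.voxels.min() < 0 or self.voxels.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
        if self.binary and not np.all(np.isin(self.voxels, (0.0, 1.0))):
            raise ValueError("binary mask contains values outside {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        if not self.binary:
            raise ValueError("voxel_count is defined for binary masks only")
        return int(self.voxels.sum())

    @property
    def volume_ml(self) -> float:
        """Physical mask volume in millilitres."""
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def as_bool(self) -> np.ndarray:
        return self.voxels > 0.5

    def binarized(self, threshold: float = 0.5) -> "SegMask":
        return SegMask(
            (self.voxels > threshold).astype(np.float64),
            binary=True,
            spacing=self.spacing,
            patient_id=self.patient_id,
        )
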