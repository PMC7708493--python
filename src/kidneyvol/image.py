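"""Core in-memory containers for station volumes and label masks.

Axis convention, fixed package-wide: ``data[row, column, slice]`` where

* axis 0 (row)    = anterior--posterior (AP),
* axis 1 (column) = left--right (LR); the subject's LEFT side is at
  *increasing* column index,
* axis 2 (slice)  = longitudinal / superior--inferior (SI).

``origin_mm`` is the physical position of voxel ``(0, 0, 0)`` on the subject
axes and is what aligns overlapping imaging stations along the longitudinal
axis. Voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VolumeImage", "LabelVolume"]


@dataclass
class VolumeImage:
    """A 3-D scalar image grid with voxel spacing and origin in mm.

    Parameters
    ----------
    data : ndarray, shape (AP, LR, SI)
        Voxel intensities.
    spacing_mm : tuple of float
        Voxel edge lengths in mm, one per axis; all strictly positive.
    origin_mm : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    channel : {"water", "fat"}
        Which Dixon-type signal the volume carries.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel: str = "water"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must be 3-D, got {self.data.ndim}-D array"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """A copy of this volume carrying different voxel data."""
        return replace(self, data=data)


@dataclass
class LabelVolume:
    """A kidney mask aligned voxel-for-voxel with a :class:`VolumeImage`.

    ``data`` holds either hard binary labels (0/1) or per-voxel foreground
    probabilities in [0, 1]; :attr:`binary` reports which.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label data must be 3-D, got {self.data.ndim}-D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def binary(self) -> bool:
        vals = np.unique(self.data)
        return bool(np.isin(vals, (0, 1)).all())

    def as_bool(self) -> np.ndarray:
        """Hard mask: probabilities are thresholded at 0.5 (>= is kidney)."""
        if self.data.dtype == bool:
            return self.data
        return self.data >= 0.5

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def volume_cm3(self) -> float:
        """Mask volume: voxel count x physical voxel volume, in cm^3."""
        return float(self.as_bool().sum()) * self.voxel_volume_mm3 / 1000.0
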