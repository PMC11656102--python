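"""Core image containers: 3D voxel grids with physical voxel dimensions.

Volumes are always carried in mm^3; voxel sizes are mm per axis. Label
grids hold non-negative integer label ids with 0 reserved for background.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntensityImage", "LabelImage", "Atlas"]


def _check_voxel_size(voxel_size: tuple[float, float, float]) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 or not np.isfinite(v) for v in vs):
        raise ValueError(f"voxel_size must be three positive lengths (mm), got {voxel_size!r}")
    return vs


@dataclass(frozen=True)
class IntensityImage:
    """A 3D grid of real-valued intensities with physical voxel size in mm."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"intensity grid must be 3D, got shape {values.shape}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_size", _check_voxel_size(self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class LabelImage:
    """A 3D grid of integer label ids (>= 0, with 0 = background)."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"label grid must be 3D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.array_equal(rounded, labels):
                raise ValueError("label grid must hold integer label ids")
            labels = rounded.astype(np.int32)
        if labels.size and labels.min() < 0:
            raise ValueError("label ids must be non-negative")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "voxel_size", _check_voxel_size(self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class Atlas:
    """An expert-labeled image: paired intensity and label grids on one grid."""

    id: str
    intensity: IntensityImage
    labels: LabelImage = field(repr=False)

    def __post_init__(self) -> None:
        if self.intensity.shape != self.labels.shape:
            raise ValueError(
                f"atlas {self.id!r}: intensity shape {self.intensity.shape} != "
                f"label shape {self.labels.shape}"
            )
        if self.intensity.voxel_size != self.labels.voxel_size:
            raise ValueError(f"atlas {self.id!r}: intensity and label voxel_size differ")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.intensity.voxel_size
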