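"""Core spatial types: image grid, CT volume, and labeled center points.

Axis convention
---------------
Arrays are indexed ``values[ix, iy, iz]`` with spacing ``(sx, sy, sz)`` in mm;
``sz`` is the slice thickness.  The voxel center of index ``i`` sits at
``origin + i * spacing`` (axis-aligned physical frame; oblique orientations
are rejected at load time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["ImageGrid", "CTVolume", "PointLabel", "PointClass"]


class PointClass(str, Enum):
    """Class of a labeled center point: bone metastasis or healthy bone."""

    BM = "BM"
    HB = "HB"


@dataclass(frozen=True)
class ImageGrid:
    """Physical geometry of a 3D raster: origin (mm), spacing (mm), shape.

    The index->mm map is affine, axis-aligned and invertible:
    ``mm = origin + index * spacing``.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(int(n) <= 0 or int(n) != n for n in self.shape):
            raise ValueError(f"shape must be positive integers, got {self.shape}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    def index_to_mm(self, index) -> np.ndarray:
        """Physical coordinates (mm) of voxel center(s) at ``index`` (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def mm_to_index(self, position) -> np.ndarray:
        """Continuous voxel index of physical position(s) in mm (..., 3)."""
        pos = np.asarray(position, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_mm(self, position) -> bool:
        """True if ``position`` lies inside the grid's physical extent.

        The extent spans the outer faces of the boundary voxels, i.e.
        ``[origin - s/2, origin + (n-1+1/2) * s]`` per axis.
        """
        idx = self.mm_to_index(position)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.shape) - 0.5))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-center physical coordinates (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )


@dataclass
class CTVolume:
    """A scalar Hounsfield-Unit field on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")


@dataclass(frozen=True)
class PointLabel:
    """An expert-identified center point: mm position + BM/HB class label."""

    patient_id: str
    position: tuple[float, float, float]
    label: PointClass
    annotator: str | None = None
    point_id: str = field(default="")

    def __post_init__(self) -> None:
        if len(self.position) != 3:
            raise ValueError("position must be a 3-vector (mm)")
        pos = tuple(float(v) for v in self.position)
        if not all(np.isfinite(pos)):
            raise ValueError(f"position must be finite, got {pos}")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "label", PointClass(self.label))
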