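"""Core voxel containers shared by every pipeline stage.

Conventions (fixed for the whole package):

* axis order is ``(depth, row, col)``; index 0 of the depth axis is the
  tooth side of the interface,
* voxels are isotropic cubes of edge ``voxel_size`` millimetres,
* the centre of voxel ``(i, j, k)`` sits at ``((i + 0.5) * voxel_size, ...)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Volume3D:
    """A reconstructed grayscale micro-CT volume (or a synthetic stand-in)."""

    voxels: np.ndarray
    voxel_size: float  # mm, isotropic

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("Volume3D requires a non-empty 3D voxel grid")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class AdhesiveMask:
    """Binary mask of the adhesive phase, same grid as the source volume."""

    mask: np.ndarray
    voxel_size: float  # mm

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3 or self.mask.size == 0:
            raise ValueError("AdhesiveMask requires a non-empty 3D grid")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        """Physical volume of the masked phase, exactly count x voxel_size^3."""
        return self.voxel_count * self.voxel_size**3


@dataclass
class ThicknessMap:
    """Per-voxel local layer width w (mm); NaN outside the mask."""

    values: np.ndarray
    voxel_size: float  # mm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("ThicknessMap requires a 3D grid")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined]
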