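"""Voxel-grid geometry shared by all volumes.

Convention: integer voxel indices, 0-based; the physical position of a voxel
is ``index * spacing`` (voxel centres), axes ordered (x, y, z) in RAS.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Reconstructed (interpolated) voxel spacing of the imaging protocol, mm.
SPACING_INTERPOLATED = (1.3, 1.3, 3.0)
#: Acquired voxel spacing before interpolation, mm.
SPACING_ACQUISITION = (3.6, 2.5, 4.8)


@dataclass(frozen=True)
class VoxelGeometry:
    """Shape (voxels per axis) and physical spacing (mm per voxel) of a grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = SPACING_INTERPOLATED

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("geometry is three-dimensional")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        """4x4 RAS affine with spacing on the diagonal, origin at voxel (0,0,0)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        return aff

    def check_same(self, other: "VoxelGeometry") -> None:
        if self.shape != other.shape or not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"geometry mismatch: {self} vs {other}")
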