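"""Voxel-grid descriptor shared by every stage.

Axis convention, used everywhere in the package: arrays are indexed
``(z, y, x)`` with ``z = 0`` at the skin surface and z increasing downward
(into the skin).  Spacing is in micrometres.  All depth intervals are
half-open ``[lo, hi)`` and all indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid", "DEFAULT_SPACING_UM", "DEFAULT_SHAPE"]

#: Default isotropic voxel pitch (µm).  The acquisition this emulates scans at a
#: 30 µm lateral step; the axial pitch of the reconstructed volumes is not a
#: fixed device property, so the synthetic grid defaults to isotropic 30 µm and
#: the spacing is configurable throughout.
DEFAULT_SPACING_UM: tuple[float, float, float] = (30.0, 30.0, 30.0)

#: Default desk-scale grid (z, y, x) ≈ 1.9 × 3.8 × 3.8 mm at 30 µm voxels.
DEFAULT_SHAPE: tuple[int, int, int] = (64, 128, 128)


@dataclass(frozen=True)
class VoxelGrid:
    """Shape and physical spacing of a 3D scan grid.

    Parameters
    ----------
    shape
        ``(nz, ny, nx)`` voxel counts; z is depth.
    spacing_um
        ``(dz, dy, dx)`` voxel pitch in micrometres, all strictly positive.
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(
                f"spacing_um must be three positive floats, got {self.spacing_um}"
            )
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_um", tuple(float(s) for s in self.spacing_um))

    @property
    def nz(self) -> int:
        return self.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) of the grid in µm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_um))

    def depth_um(self, z_index: np.ndarray | float) -> np.ndarray | float:
        """Depth below the surface (µm) of a z slice index (voxel centres)."""
        return (np.asarray(z_index) + 0.5) * self.spacing_um[0]

    def voxel_centers_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (z, y, x) physical coordinates of voxel centres, µm."""
        nz, ny, nx = self.shape
        dz, dy, dx = self.spacing_um
        z = (np.arange(nz, dtype=float)[:, None, None] + 0.5) * dz
        y = (np.arange(ny, dtype=float)[None, :, None] + 0.5) * dy
        x = (np.arange(nx, dtype=float)[None, None, :] + 0.5) * dx
        return z, y, x
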