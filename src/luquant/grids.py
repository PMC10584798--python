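"""Voxel grids and world <-> index coordinate mapping.

A :class:`VoxelGrid` is an axis-aligned regular grid.  Index ``(0, 0, 0)``
has its *centre* at ``origin`` (world mm); axis ``i`` advances by
``spacing[i]`` mm per index step.  Array axes are ordered ``(x, y, z)``
with ``z`` the scanner (axial) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive on all axes, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        if self.origin is None:
            # centre the grid on the world origin
            origin = tuple(-(n - 1) / 2.0 * d for n, d in zip(shape, spacing))
        else:
            origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "origin", origin)

    # ------------------------------------------------------------------
    @classmethod
    def isotropic(cls, n: int, spacing: float) -> "VoxelGrid":
        """Cube of ``n`` voxels per axis with isotropic ``spacing`` mm,
        centred on the world origin."""
        return cls((n, n, n), (spacing, spacing, spacing))

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge-to-edge extent per axis [mm]."""
        return tuple(n * d for n, d in zip(self.shape, self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates [mm] of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate arrays (broadcastable) of all voxel centres."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to fractional indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.array(self.origin)) / np.array(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) indices (..., 3) to world mm coordinates."""
        i = np.asarray(idx, dtype=float)
        return i * np.array(self.spacing) + np.array(self.origin)

    def affine(self) -> np.ndarray:
        """4x4 index->world affine (NIfTI convention)."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )
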