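"""Regular 3D grids with isocenter-referenced coordinates.

All spatial quantities are in millimetres unless a name says otherwise.
The grid origin is the coordinate of the centre of voxel (0, 0, 0) and is
chosen so that the geometric centre of the grid maps to (0, 0, 0) mm — the
scanner isocenter convention used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Shape, spacing and origin of a regular 3D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels per axis ``(Nx, Ny, Nz)``; every entry must be >= 8.
    spacing_mm
        Voxel spacing per axis in mm; strictly positive.
    origin_mm
        Coordinate (mm) of the centre of voxel ``(0, 0, 0)``. Defaults to the
        isocenter-referenced value ``-(n - 1) / 2 * spacing`` per axis.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    origin_mm: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("GridSpec is three-dimensional")
        if any(n < 8 for n in shape):
            raise ValueError(f"every grid axis needs >= 8 voxels, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacings must be positive, got {spacing}")
        if self.origin_mm is None:
            origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        else:
            origin = tuple(float(o) for o in self.origin_mm)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        """Field of view per axis (mm)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinates in mm."""
        return tuple(
            o + s * np.arange(n)
            for n, s, o in zip(self.shape, self.spacing_mm, self.origin_mm)
        )

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable meshgrid of voxel-centre coordinates (mm)."""
        ax, ay, az = self.axes_mm()
        return np.meshgrid(ax, ay, az, indexing="ij")

    def positions_mm(self) -> np.ndarray:
        """All voxel-centre positions, shape ``(n_voxels, 3)``, C order."""
        X, Y, Z = self.coords_mm()
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


DEFAULT_GRID = GridSpec(shape=(32, 40, 40), spacing_mm=(8.0, 8.0, 8.0))
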