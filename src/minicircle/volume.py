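"""Density volumes: 3-D scalar grids with physical voxel spacing.

Coordinate convention (used package-wide): volumes are indexed ``[ix, iy, iz]``
with 0-based indices; the *center* of voxel ``(i, j, k)`` sits at
``origin + (i, j, k) * voxel_size`` in Angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["DensityVolume"]


@dataclass
class DensityVolume:
    """A 3-D scalar grid holding (synthetic or experimental) cryo-ET density.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar density values (stored as float32).
    voxel_size : float
        Isotropic voxel spacing in Angstroms.
    origin : ndarray, shape (3,)
        Position (Angstroms) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a non-empty 3-D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density values must be finite")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.data.copy(), self.voxel_size,
                             self.origin.copy())

    # -- coordinate transforms --------------------------------------------

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (Angstroms) to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.voxel_size

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(indices, dtype=float) * self.voxel_size + self.origin

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(self.origin[k] + self.voxel_size * np.arange(self.shape[k])
                     for k in range(3))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which points fall inside the grid (interpolatable)."""
        idx = self.world_to_index(points)
        hi = np.array(self.shape) - 1
        return np.all((idx >= 0) & (idx <= hi), axis=-1)

    # -- sampling ----------------------------------------------------------

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated density at world coordinates.

        Points outside the grid evaluate against zero-padded boundaries.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = self.world_to_index(pts)
        vals = map_coordinates(self.data.astype(float), idx.T, order=1,
                               mode="constant", cval=0.0)
        return vals if np.asarray(points).ndim > 1 else float(vals[0])
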