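"""Voxel-grid containers shared across the pipeline.

Convention: right-handed RAS world coordinates in millimeters, 0-based
voxel indices, and the center of voxel (0, 0, 0) at ``origin``.  The
NIfTI affine written by :mod:`navmargin.io` encodes exactly this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridBase", "Volume", "LabelMask", "DistanceField"]


@dataclass
class GridBase:
    """Common geometry of a voxel grid (dims, isotropic spacing, origin)."""

    spacing: float
    origin: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")

    @property
    def dims(self) -> tuple:
        return self._array().shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.spacing
        aff[:3, 3] = self.origin
        return aff

    def axis_coords(self):
        """World coordinates of voxel centers along each axis."""
        return [self.origin[i] + self.spacing * np.arange(self.dims[i]) for i in range(3)]

    def world_to_index(self, points):
        """Continuous (fractional) voxel indices of world points."""
        return (np.atleast_2d(np.asarray(points, dtype=float)) - self.origin) / self.spacing

    def index_to_world(self, idx):
        return np.atleast_2d(np.asarray(idx, dtype=float)) * self.spacing + self.origin

    def contains(self, points) -> np.ndarray:
        """True where world points fall inside the voxel-center lattice."""
        idx = self.world_to_index(points)
        upper = np.asarray(self.dims) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=1)

    def _array(self) -> np.ndarray:  # pragma: no cover - overridden
        raise NotImplementedError


@dataclass
class Volume(GridBase):
    """Scalar intensity volume (synthetic CBCT surrogate)."""

    data: np.ndarray = field(default=None)

    def __post_init__(self):
        super().__post_init__()
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")

    def _array(self):
        return self.data


@dataclass
class LabelMask(GridBase):
    """Binary occupancy mask on a voxel grid."""

    voxels: np.ndarray = field(default=None)

    def __post_init__(self):
        super().__post_init__()
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")

    def _array(self):
        return self.voxels

    @property
    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class DistanceField(GridBase):
    """Per-voxel signed distance (mm); negative strictly inside."""

    values: np.ndarray = field(default=None)

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("distance values must be 3D")

    def _array(self):
        return self.values

    def sample(self, points):
        """Trilinear interpolation at world points; errors out of bounds.

        Raises
        ------
        ValueError
            Naming the first offending point if any sample falls outside
            the voxel-center lattice.
        """
        from scipy.ndimage import map_coordinates

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = self.world_to_index(pts)
        inside = self.contains(pts)
        if not np.all(inside):
            bad = pts[~inside][0]
            raise ValueError(
                f"sample point {tuple(np.round(bad, 3))} mm lies outside the "
                f"distance-field grid"
            )
        return map_coordinates(self.values, idx.T, order=1, mode="nearest")
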