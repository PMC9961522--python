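"""Voxel-grid primitives shared by every stage of the pipeline.

Conventions (fixed throughout the package):

* volumes are ``numpy`` arrays of shape ``(nx, ny, nz)`` on an isotropic grid;
* voxel centers sit at ``origin + (i + 0.5) * h`` along each axis, with ``h``
  the voxel size in meters;
* voxel indexing is 0-based and flat indices use Fortran order, i.e. x is the
  fastest axis and z the slowest.

All lengths are meters, phases radians, conductivities S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Magnetic permeability of vacuum (H/m), exact by convention here.
MU0 = 4.0e-7 * np.pi


def flat_indices(coords: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Fortran-order flat index of integer voxel coordinates ``(N, 3)``."""
    coords = np.asarray(coords)
    return np.ravel_multi_index(
        (coords[..., 0], coords[..., 1], coords[..., 2]), shape, order="F"
    )


def unflatten(flat: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`flat_indices`; returns ``(N, 3)`` integer coordinates."""
    ix, iy, iz = np.unravel_index(np.asarray(flat), shape, order="F")
    return np.stack([ix, iy, iz], axis=-1)


def voxel_centers_1d(n: int, voxel_size: float, origin: float = 0.0) -> np.ndarray:
    return origin + (np.arange(n) + 0.5) * voxel_size


@dataclass
class Volume:
    """A scalar field sampled on an isotropic voxel grid.

    Used both for transceive-phase volumes (rad) and transmit-magnitude
    (|B1+|^2, arbitrary units) volumes; ``scan_id`` tags the acquisition.
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scan_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("Volume values must be a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """Physical side lengths of the grid (m)."""
        return np.asarray(self.shape) * self.voxel_size

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-center coordinate arrays (m)."""
        axes = [
            voxel_centers_1d(n, self.voxel_size, o)
            for n, o in zip(self.shape, self.origin)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)


def grid_center(shape: tuple[int, int, int], voxel_size: float,
                origin: np.ndarray | None = None) -> np.ndarray:
    """Geometric center of the grid in physical coordinates (m)."""
    c = 0.5 * np.asarray(shape) * voxel_size
    if origin is not None:
        c = c + np.asarray(origin, dtype=float)
    return c
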