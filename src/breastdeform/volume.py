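"""In-memory 3D image volume with world-coordinate metadata.

The package-wide axis convention (documented here once, used everywhere):
index axis 0 -> world +x (subject right, sagittal slice index),
index axis 1 -> world +y (posterior -> anterior),
index axis 2 -> world +z (inferior -> superior).
Prone gravity pulls the breast anteriorly away from the chest wall (+y);
supine gravity acts posteriorly (-y). Both are configurable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageVolume:
    """A 3D scalar grid plus a voxel->world affine (mm).

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        Scalar intensities (or labels).
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index -> world-mm transform. Must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @classmethod
    def from_spacing(cls, data: np.ndarray, spacing_mm) -> "ImageVolume":
        spacing_mm = np.broadcast_to(np.asarray(spacing_mm, float), (3,))
        affine = np.diag([*spacing_mm, 1.0])
        return cls(data, affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm, one per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_world(self, ijk) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz) -> np.ndarray:
        """Map world mm coordinates (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume sharing this volume's geometry."""
        return ImageVolume(np.asarray(data), self.affine.copy())
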