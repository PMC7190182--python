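"""Voxel volume container with world (RAS, mm) geometry.

All downstream measurements are made in world millimetres; the volume carries
a voxel->world affine in the RAS convention (+x right, +y anterior,
+z superior). Voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["LabeledVolume", "read_nifti", "write_nifti"]


@dataclass
class LabeledVolume:
    """A 3D intensity or integer-label volume plus voxel->world affine.

    Parameters
    ----------
    voxels
        3D array. Integer dtypes are treated as label maps, floats as
        intensities.
    affine
        4x4 voxel->world (mm) matrix, RAS convention. Must be invertible.
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def spacing_mm(self) -> np.ndarray:
        """Per-axis voxel spacing (mm): column norms of the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def is_label(self) -> bool:
        return np.issubdtype(self.voxels.dtype, np.integer)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N,3) voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (N,3) world mm coordinates to (fractional) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(self.voxels.copy(), self.affine.copy())


def read_nifti(path: str | Path) -> LabeledVolume:
    """Load a NIfTI volume, preserving its affine."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return LabeledVolume(data, img.affine)


def write_nifti(vol: LabeledVolume, path: str | Path) -> None:
    """Write a volume as NIfTI, preserving the affine."""
    data = vol.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))
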