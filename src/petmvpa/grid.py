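"""Voxel lattice geometry and NIfTI-1 round-tripping.

Volumes live on a regular 3D lattice in a common template space; the
affine maps voxel indices (i, j, k) to millimetre coordinates.  Only
isotropic voxels (default 2 mm, the template resolution used throughout)
are produced by the synthetic generator, but the affine machinery is
general.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a scalar volume: shape, voxel size and origin.

    Parameters
    ----------
    shape
        Voxel counts per axis, each >= 1.
    voxel_size_mm
        Isotropic voxel edge length in millimetres (> 0).
    origin_mm
        Template-space coordinate of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float = 2.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three counts >= 1, got {self.shape}")
        if not self.voxel_size_mm > 0:
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-mm affine (diagonal scaling plus origin shift)."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk * self.voxel_size_mm + np.asarray(self.origin_mm)

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm coordinates (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin_mm)) / self.voxel_size_mm

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open mm-coordinate grids along each axis (broadcastable)."""
        axes = [
            self.origin_mm[a] + np.arange(self.shape[a]) * self.voxel_size_mm
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    @classmethod
    def from_affine(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "GridSpec":
        diag = np.diag(affine)[:3]
        if not np.allclose(np.abs(diag), np.abs(diag[0])):
            raise ValueError("anisotropic affine not supported")
        return cls(tuple(shape), float(abs(diag[0])), tuple(affine[:3, 3]))


def save_volume(volume: np.ndarray, grid: GridSpec, path) -> None:
    """Write a volume as NIfTI-1 with the grid's affine."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, GridSpec]:
    """Read a NIfTI-1 volume and recover its GridSpec from the affine."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    grid = GridSpec.from_affine(data.shape, img.affine)
    return data, grid
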