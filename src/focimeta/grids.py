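"""MNI-aligned voxel grids and scalar statistic maps.

Thin containers shared by the ALE and connectivity stages.  A
:class:`VolumeGrid` is a 3-D voxel lattice with an affine taking voxel
indices to mm coordinates (RAS), plus an inclusion mask; a
:class:`StatMap` is a scalar field on a grid with a kind tag (MA, ALE, p,
z, t, binary).  NIfTI-1 round-trip goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import GridMismatchError

__all__ = ["VolumeGrid", "StatMap", "save_map", "load_map"]

#: Default MNI bounding box in mm: [-90, 90] x [-126, 90] x [-72, 108].
MNI_BOX = ((-90.0, 90.0), (-126.0, 90.0), (-72.0, 108.0))


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel lattice with a voxel->mm affine and an inclusion mask."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "affine", aff)
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != tuple(self.shape):
                raise ValueError("mask shape does not match grid shape")
            object.__setattr__(self, "mask", m)

    @classmethod
    def mni152(cls, voxel_size: float = 2.0) -> "VolumeGrid":
        """Isotropic grid covering the default MNI bounding box."""
        lo = np.array([b[0] for b in MNI_BOX])
        hi = np.array([b[1] for b in MNI_BOX])
        shape = tuple(int(np.floor((h - l) / voxel_size)) + 1 for l, h in zip(lo, hi))
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
        aff[:3, 3] = lo
        return cls(shape=shape, affine=aff)

    @classmethod
    def box(cls, lo, hi, voxel_size: float) -> "VolumeGrid":
        """Small isotropic grid over an arbitrary mm box (test/desk scale)."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        shape = tuple(int(np.floor((h - l) / voxel_size)) + 1 for l, h in zip(lo, hi))
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
        aff[:3, 3] = lo
        return cls(shape=shape, affine=aff)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.mask

    def voxel_to_mm(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz) -> np.ndarray:
        """Continuous voxel coordinates (not rounded)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def same_as(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def require_same(self, other: "VolumeGrid") -> None:
        if not self.same_as(other):
            raise GridMismatchError("maps do not share a voxel grid")


@dataclass
class StatMap:
    """A scalar field on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray
    kind: str = "ALE"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid shape")
        self.values = v

    def masked(self) -> np.ndarray:
        """Values with out-of-mask voxels set to 0."""
        out = self.values.copy()
        out[~self.grid.effective_mask()] = 0.0
        return out

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "StatMap":
        return StatMap(self.grid, values, kind or self.kind)


def save_map(m: StatMap, path) -> None:
    img = nib.Nifti1Image(m.values.astype(np.float64), m.grid.affine)
    nib.save(img, str(path))


def load_map(path, kind: str = "ALE") -> StatMap:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = VolumeGrid(shape=tuple(data.shape), affine=np.asarray(img.affine))
    return StatMap(grid=grid, values=data, kind=kind)
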