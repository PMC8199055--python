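"""Voxel-grid geometry and the in-memory image containers.

All images carry a 4x4 affine mapping 0-based voxel indices to world
coordinates in mm (voxel-centre convention, as in NIfTI). Two grids that
describe the same physical field of view therefore live in a shared world
space and can be resampled against each other without further registration.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np

__all__ = [
    "Grid",
    "ParametricMap",
    "SegmentationMask",
    "DWIVolume",
]


@dataclass(frozen=True)
class Grid:
    """A 3D voxel lattice: shape plus an invertible index->world affine."""

    shape: Tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"grid shape must be a positive integer triple, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        aff = aff.copy()
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @classmethod
    def centered(cls, shape, voxel_size) -> "Grid":
        """Axis-aligned grid whose field of view is centred on the world origin.

        The voxel centre of index ``i`` along an axis sits at
        ``(i + 0.5) * dv - FOV/2``, so grids of different resolution built from
        the same field of view share world space exactly.
        """
        shape = tuple(int(n) for n in shape)
        voxel_size = np.asarray(voxel_size, dtype=float)
        fov = np.array(shape) * voxel_size
        affine = np.eye(4)
        affine[:3, :3] = np.diag(voxel_size)
        affine[:3, 3] = -fov / 2.0 + voxel_size / 2.0
        return cls(shape, affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Physical voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)

    @property
    def fov_mm(self) -> np.ndarray:
        return np.array(self.shape) * self.voxel_size

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map an (..., 3) array of (fractional) voxel indices to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ np.asarray(self.affine)[:3, :3].T + np.asarray(self.affine)[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(np.asarray(self.affine))
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.index_to_world(idx)

    def same_as(self, other: "Grid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


def _require_same_grid(a: Grid, b: Grid, what: str) -> None:
    if not a.same_as(b):
        raise ValueError(f"grid mismatch: {what} must share the same grid")


@dataclass
class ParametricMap:
    """A scalar MD or MK volume. Invalid voxels are marked NaN.

    MD is carried in units of 1e-3 mm^2/s; MK is dimensionless.
    """

    values: np.ndarray
    kind: Literal["MD", "MK"]
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("map shape does not match grid")
        if self.kind not in ("MD", "MK"):
            raise ValueError(f"kind must be 'MD' or 'MK', got {self.kind!r}")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class SegmentationMask:
    """A binary voxel set on a grid."""

    values: np.ndarray
    grid: Grid
    provenance: str = "auto"  # auto | manual | truth

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary")
            vals = vals.astype(bool)
        if vals.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        self.values = vals

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted signal with its grid and acquisition scheme."""

    signal: np.ndarray
    grid: Grid
    scheme: "AcquisitionScheme"  # noqa: F821 - forward ref, avoids import cycle

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise ValueError("DWI signal must be 4D")
        if self.signal.shape[:3] != self.grid.shape:
            raise ValueError("DWI spatial shape does not match grid")
        if self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"DWI has {self.signal.shape[3]} volumes but the scheme lists "
                f"{len(self.scheme)}"
            )
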