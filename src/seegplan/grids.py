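"""Voxel grid geometry: shape, spacing, origin and world/voxel conversions.

A :class:`Grid` describes an axis-aligned isotropic-or-anisotropic voxel
lattice.  World coordinates are millimetres; the centre of voxel ``(0,0,0)``
sits at ``origin + spacing/2`` so that a grid centred on the head phantom has
its world origin in the middle of the volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Axis-aligned voxel lattice in millimetre world coordinates."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (-48.0, -48.0, -48.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError("Grid is 3-D: shape must have three entries")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- conversions ---------------------------------------------------
    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices (possibly fractional) to world mm (voxel centres)."""
        idx = np.asarray(idx, dtype=float)
        return self.origin_arr + (idx + 0.5) * self.spacing_arr

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """World mm to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.origin_arr) / self.spacing_arr - 0.5

    def voxel_centers(self) -> np.ndarray:
        """All voxel-centre world coordinates, shape ``(*shape, 3)``."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI convention)."""
        mat = np.eye(4)
        mat[:3, :3] = np.diag(self.spacing_arr)
        mat[:3, 3] = self.origin_arr + 0.5 * self.spacing_arr
        return mat

    @classmethod
    def from_affine(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "Grid":
        spacing = tuple(np.diag(affine[:3, :3]).astype(float))
        origin = tuple(affine[:3, 3] - 0.5 * np.asarray(spacing))
        return cls(tuple(shape), spacing, origin)

    def same_as(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def contains_points(self, mask: np.ndarray, xyz: np.ndarray) -> np.ndarray:
        """Whether each world point falls in a True voxel of ``mask``."""
        mask = np.asarray(mask)
        if mask.shape != self.shape:
            raise ValueError("mask shape does not match grid")
        vox = np.rint(self.world_to_voxel(np.atleast_2d(xyz))).astype(int)
        inside = np.all((vox >= 0) & (vox < np.array(self.shape)), axis=1)
        out = np.zeros(len(vox), dtype=bool)
        if inside.any():
            v = vox[inside]
            out[inside] = mask[v[:, 0], v[:, 1], v[:, 2]]
        return out
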