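"""Core voxel-grid containers shared by every stage of the pipeline.

A subject's data — the intensity image, each stochastic probability sample,
the consensus mask, the ground-truth mask and all uncertainty maps — live on
one :class:`ImageGrid`.  Every multi-volume operation in the package checks
grid compatibility up front so that a spacing or shape mismatch fails loudly
instead of silently producing distances or volumes in the wrong units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "BinaryMask",
    "GridMismatchError",
    "grids_compatible",
    "require_compatible",
]

#: relative tolerance for spacing/affine agreement between grids
GRID_RTOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid do not."""


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of a 3-D voxel grid.

    Parameters
    ----------
    shape
        Voxels per axis, each >= 1.
    affine
        4x4 voxel-index -> world (mm) transform; must be invertible.
        Voxel spacing in mm is derived from the affine column norms.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three entries >= 1, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def from_spacing(
        cls, shape: tuple[int, int, int], spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ) -> "ImageGrid":
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        affine = np.diag([*spacing, 1.0])
        return cls(shape=tuple(shape), affine=affine)

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel size in mm along each axis (affine column norms)."""
        return tuple(float(n) for n in np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coordinates(self, index_array: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm coordinates."""
        idx = np.asarray(index_array, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageGrid):
            return NotImplemented
        return self.shape == other.shape and np.array_equal(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.tobytes()))


def grids_compatible(a: ImageGrid, b: ImageGrid) -> bool:
    """True iff shapes match and spacing/affine agree to relative tolerance 1e-4."""
    if a.shape != b.shape:
        return False
    scale = max(np.abs(a.affine).max(), np.abs(b.affine).max(), 1.0)
    if not np.allclose(a.affine, b.affine, rtol=GRID_RTOL, atol=GRID_RTOL * scale):
        return False
    return np.allclose(a.spacing, b.spacing, rtol=GRID_RTOL)


def require_compatible(*grids: ImageGrid, context: str = "operation") -> None:
    first = grids[0]
    for g in grids[1:]:
        if not grids_compatible(first, g):
            raise GridMismatchError(
                f"{context}: incompatible grids (shape {first.shape} vs {g.shape}, "
                f"spacing {first.spacing} vs {g.spacing})"
            )


@dataclass
class ScalarVolume:
    """A real-valued volume on an :class:`ImageGrid`.

    When ``is_probability`` is set the values are validated to lie in [0, 1];
    probability semantics are required by every entropy computation downstream.
    """

    grid: ImageGrid
    values: np.ndarray = field(repr=False)
    is_probability: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            if values.size == self.grid.n_voxels:
                values = values.reshape(self.grid.shape)
            else:
                raise ValueError(
                    f"value array shape {values.shape} does not match grid {self.grid.shape}"
                )
        if self.is_probability:
            lo, hi = float(values.min()), float(values.max())
            if lo < 0.0 or hi > 1.0:
                raise ValueError(
                    f"probability volume has values outside [0, 1]: min={lo:.6g}, max={hi:.6g}"
                )
        self.values = values

    def copy(self) -> "ScalarVolume":
        return dataclasses.replace(self, values=self.values.copy())


@dataclass
class BinaryMask:
    """A {0, 1} volume (consensus segmentation, ground truth, or aggregation mask)."""

    grid: ImageGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            if values.size == self.grid.n_voxels:
                values = values.reshape(self.grid.shape)
            else:
                raise ValueError(
                    f"mask shape {values.shape} does not match grid {self.grid.shape}"
                )
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:10]}")
        self.values = values.astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_foreground * self.grid.voxel_volume_mm3

    def astype_bool(self) -> np.ndarray:
        return self.values.astype(bool)
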