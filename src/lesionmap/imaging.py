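"""Volume data model, NIfTI I/O and mm/voxel coordinate transforms.

All stages of the pipeline share one picture of space: a ``VolumeGrid``
(shape + affine, NIfTI RAS+ convention, 0-based voxel indices) and a
``BinaryVolume`` (a boolean mask living on a grid).  Lesion masks, region
masks and overlap maps all use the same grid; grids that differ are an
error rather than a resampling job, because every image in one analysis is
assumed to already sit in a common standard (MNI) space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "BinaryVolume",
    "GridMismatchError",
    "read_mask",
    "write_mask",
    "mm_to_voxel",
    "voxel_to_mm",
    "volume_cm3",
    "toy_grid",
]

#: tolerance for affine / shape compatibility between grids
GRID_ATOL = 1e-5


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D sampling grid: voxel array shape plus a 4x4 RAS+ affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape!r}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("degenerate affine: spatial 3x3 block is singular")
        affine = affine.copy()
        affine.setflags(write=False)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the spatial affine block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def compatible(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=GRID_ATOL
        )

    def require_compatible(self, other: "VolumeGrid", context: str = "") -> None:
        if not self.compatible(other):
            suffix = f" ({context})" if context else ""
            raise GridMismatchError(
                f"incompatible grids{suffix}: shape/affine differ beyond {GRID_ATOL}"
            )


@dataclass
class BinaryVolume:
    """A boolean mask on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        self.data = data.astype(bool, copy=False)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "BinaryVolume") -> "BinaryVolume":
        self.grid.require_compatible(other.grid)
        return BinaryVolume(self.grid, self.data & other.data)

    def __or__(self, other: "BinaryVolume") -> "BinaryVolume":
        self.grid.require_compatible(other.grid)
        return BinaryVolume(self.grid, self.data | other.data)


def read_mask(path: str | Path) -> BinaryVolume:
    """Read a NIfTI volume and binarize it (values > 0.5 are foreground).

    Raises a diagnostic error naming the file for missing files, non-3-D
    volumes and degenerate affines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lesion/region mask not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim} dimensions")
    try:
        grid = VolumeGrid(data.shape, img.affine)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return BinaryVolume(grid, data > 0.5)


def write_mask(volume: BinaryVolume, path: str | Path) -> Path:
    """Write a binary mask as uint8 NIfTI; round-trips with :func:`read_mask`."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.uint8), np.asarray(volume.grid.affine))
    nib.save(img, str(path))
    return path


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # numpy's round() is banker's rounding; mm->voxel wants half-away-from-zero
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def mm_to_voxel(grid: VolumeGrid, coord_mm) -> tuple[int, int, int]:
    """Map a stereotactic mm coordinate to the nearest voxel index.

    Applies the inverse affine and rounds half-away-from-zero per axis.
    Coordinates that land outside the grid are rejected, reporting the
    offending axis.
    """
    coord_mm = np.asarray(coord_mm, dtype=float)
    inv = np.linalg.inv(np.asarray(grid.affine))
    vox = inv @ np.append(coord_mm, 1.0)
    idx = _round_half_away(vox[:3]).astype(int)
    for axis in range(3):
        if not (0 <= idx[axis] < grid.shape[axis]):
            raise ValueError(
                f"mm coordinate {tuple(coord_mm)} maps outside the grid on axis "
                f"{axis} (voxel index {idx[axis]}, valid 0..{grid.shape[axis] - 1})"
            )
    return int(idx[0]), int(idx[1]), int(idx[2])


def voxel_to_mm(grid: VolumeGrid, index) -> np.ndarray:
    """Map a voxel index to the mm coordinate of its centre."""
    index = np.asarray(index, dtype=float)
    return (np.asarray(grid.affine) @ np.append(index, 1.0))[:3]


def volume_cm3(volume: BinaryVolume) -> float:
    """Mask volume in cm^3: true-voxel count times voxel volume / 1000."""
    return volume.n_voxels * volume.grid.voxel_volume_mm3 / 1000.0


def toy_grid(n: int = 64, voxel_mm: float = 2.0) -> VolumeGrid:
    """A centred isotropic test grid (default 64^3 at 2 mm)."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (n - 1) / 2.0
    return VolumeGrid((n, n, n), affine)
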