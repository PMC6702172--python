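"""Volume and streamline I/O plus the coordinate conventions used everywhere else.

All volumes are 3-D NIfTI-1 images carried as :class:`VolumeImage`; all
streamlines live in world millimetres (RAS, the TCK convention) as
:class:`StreamlineSet`. Conversion between world mm and voxel indices happens
in exactly one place (:func:`world_to_voxel` / :func:`voxel_of_points`), with
a 0-based voxel-centre convention: integer voxel ``i`` owns the half-open
interval ``[i - 0.5, i + 0.5)`` along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np


class GeometryError(ValueError):
    """Raised when grids/affines are inconsistent or singular."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D voxel lattice bound to a voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise GeometryError(f"grid shape must be 3 positive ints, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if not np.allclose(aff[3], [0, 0, 0, 1]):
            raise GeometryError("affine last row must be (0,0,0,1)")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "shape", shape)
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, VoxelGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=1e-9)
        )

    def __hash__(self):
        return hash(self.shape)


@dataclass
class VolumeImage:
    """A scalar 3-D array bound to a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def is_mask(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def like(self, values: np.ndarray) -> "VolumeImage":
        """New image on the same grid."""
        return VolumeImage(self.grid, values)


@dataclass
class StreamlineSet:
    """An ordered collection of polylines with points in world mm."""

    streamlines: list[np.ndarray] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        cleaned = []
        for sl in self.streamlines:
            arr = np.asarray(sl, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
                raise ValueError("each streamline must be an (n>=1, 3) array")
            if not np.isfinite(arr).all():
                raise ValueError("streamline contains non-finite coordinates")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]

    def subset(self, indices: Sequence[int], provenance: str | None = None) -> "StreamlineSet":
        return StreamlineSet(
            [self.streamlines[i] for i in indices],
            provenance if provenance is not None else self.provenance,
        )


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(path) -> VolumeImage:
    """Read a 3-D NIfTI-1 volume; the file's affine is honoured exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"expected a 3-D volume, got ndim={data.ndim} in {path}")
    return VolumeImage(VoxelGrid(data.shape, img.affine), data.astype(np.float64))


def write_volume(img: VolumeImage, path) -> Path:
    """Write a VolumeImage as NIfTI-1 (float64 payload, lossless round-trip)."""
    path = Path(path)
    nii = nib.Nifti1Image(np.asarray(img.values, dtype=np.float64), img.grid.affine)
    nib.save(nii, str(path))
    return path


# ---------------------------------------------------------------------------
# TCK streamlines


def read_streamlines(path) -> StreamlineSet:
    """Read a TCK tractogram; points come back in world mm (RAS)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tck = nib.streamlines.load(str(path))
    return StreamlineSet([np.asarray(s, dtype=float) for s in tck.streamlines],
                         provenance=str(path))


def write_streamlines(s: StreamlineSet, path) -> Path:
    """Write a StreamlineSet as TCK (world mm, RAS)."""
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(sl, dtype=np.float32) for sl in s.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))
    return path


# ---------------------------------------------------------------------------
# Coordinates


def world_to_voxel(points: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Map world-mm points to continuous voxel coordinates (0-based).

    The forward affine applied to the result recovers the input to well below
    1e-9 mm for sane affines.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(grid.affine)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_world(coords: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Map continuous voxel coordinates to world mm."""
    c = np.atleast_2d(np.asarray(coords, dtype=float))
    return c @ grid.affine[:3, :3].T + grid.affine[:3, 3]


def voxel_of_points(points: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Integer voxel containing each world point: i owns [i-0.5, i+0.5)."""
    return np.floor(world_to_voxel(points, grid) + 0.5).astype(np.int64)
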