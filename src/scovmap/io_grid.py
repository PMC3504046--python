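"""Volumetric grids, voxel/world geometry, and cohort assembly.

The analyses in this package run on cohorts of gray-matter (GM) density
volumes that have already been spatially normalized to a common template,
segmented, and modulated.  This module provides the shared geometry
(:class:`VolumeGrid`), sets of voxels on that geometry (:class:`VoxelSet`),
and the container tying a 4-D GM stack to a per-subject covariate table
(:class:`SubjectCohort`), together with NIfTI-1/TSV round-trip I/O.

Conventions
-----------
* Voxel indices are 0-based triples ``(i, j, k)``.
* World coordinates are millimetres in the frame of the NIfTI affine
  (RAS/MNI convention for template-space data).
* Continuous voxel coordinates are rounded to the nearest voxel with
  round-half-up per axis (``floor(x + 0.5)``); after floating-point affine
  arithmetic exact ties do not occur in practice.
* On disk, volumes are NIfTI-1 with 32-bit float data; a 4-D stack carries
  subjects on the 4th axis.  Subject tables are TSV with an ``id`` and
  ``group`` column plus optional ``tbv``, ``age`` and ``ados_si`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "VoxelSet",
    "SubjectCohort",
    "GridMismatchError",
    "CohortShapeError",
    "OutsideGridError",
    "load_cohort",
    "save_cohort",
    "load_volume",
    "save_volume",
]

OPTIONAL_TABLE_COLUMNS = ("tbv", "age", "ados_si")


class GridMismatchError(ValueError):
    """Volumes in one cohort do not share a single grid."""


class CohortShapeError(ValueError):
    """Number of volumes and number of table rows disagree."""


class OutsideGridError(ValueError):
    """A world-space point maps outside the volume grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """Regular 3-D sampling grid in template space.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis.
    affine : (4, 4) ndarray
        Homogeneous matrix mapping 0-based voxel indices to world mm.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine 3x3 block is singular")
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge length per axis in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_to_world(self, ijk) -> np.ndarray:
        """Map voxel indices (``(..., 3)``) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel_continuous(self, mm) -> np.ndarray:
        """Map world mm coordinates to continuous voxel coordinates."""
        mm = np.asarray(mm, dtype=float)
        inv = np.linalg.inv(self.affine)
        return mm @ inv[:3, :3].T + inv[:3, 3]

    def world_to_voxel(self, mm) -> np.ndarray:
        """Nearest-voxel index for a world point (round-half-up per axis).

        Raises
        ------
        OutsideGridError
            If the nearest voxel center lies outside the grid.
        """
        cont = self.world_to_voxel_continuous(mm)
        idx = np.floor(cont + 0.5).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.dims)[..., :]):
            raise OutsideGridError(
                f"point {np.asarray(mm).tolist()} maps to voxel {idx.tolist()} "
                f"outside grid dims {self.dims}"
            )
        return idx

    def contains_voxel(self, ijk) -> bool:
        ijk = np.asarray(ijk)
        return bool(np.all(ijk >= 0) and np.all(ijk < np.asarray(self.dims)))

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "VolumeGrid":
        return cls(dims=tuple(img.shape[:3]), affine=np.asarray(img.affine))


@dataclass(eq=False)
class VoxelSet:
    """A set of voxels on a :class:`VolumeGrid`, stored as a boolean field."""

    grid: VolumeGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {mask.shape} does not match grid dims {self.grid.dims}"
            )
        self.mask = mask

    @classmethod
    def empty(cls, grid: VolumeGrid) -> "VoxelSet":
        return cls(grid, np.zeros(grid.dims, dtype=bool))

    @classmethod
    def from_indices(cls, grid: VolumeGrid, indices) -> "VoxelSet":
        mask = np.zeros(grid.dims, dtype=bool)
        indices = np.atleast_2d(np.asarray(indices, dtype=int))
        if indices.size:
            if np.any(indices < 0) or np.any(indices >= np.asarray(grid.dims)):
                raise ValueError("voxel indices outside grid dims")
            mask[tuple(indices.T)] = True
        return cls(grid, mask)

    @property
    def indices(self) -> np.ndarray:
        """(N, 3) array of member voxel indices in C order."""
        return np.argwhere(self.mask)

    def __len__(self) -> int:
        return int(self.mask.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelSet):
            return NotImplemented
        return self.grid.matches(other.grid) and np.array_equal(self.mask, other.mask)

    def _check_same_grid(self, other: "VoxelSet") -> None:
        if not self.grid.matches(other.grid):
            raise GridMismatchError("voxel sets live on different grids")

    def union(self, other: "VoxelSet") -> "VoxelSet":
        self._check_same_grid(other)
        return VoxelSet(self.grid, self.mask | other.mask)

    def intersection(self, other: "VoxelSet") -> "VoxelSet":
        self._check_same_grid(other)
        return VoxelSet(self.grid, self.mask & other.mask)

    def difference(self, other: "VoxelSet") -> "VoxelSet":
        self._check_same_grid(other)
        return VoxelSet(self.grid, self.mask & ~other.mask)

    def issubset(self, other: "VoxelSet") -> bool:
        self._check_same_grid(other)
        return bool(np.all(other.mask[self.mask]))

    __or__ = union
    __and__ = intersection
    __sub__ = difference


@dataclass
class SubjectCohort:
    """A 4-D GM stack plus its per-subject covariate table.

    ``gm`` is stored with subjects on the leading axis, ``(n, X, Y, Z)``,
    aligned with the rows of ``table``.  GM values are unitless tissue
    densities, typically in ``[0, ~2]`` after modulation.
    """

    grid: VolumeGrid
    gm: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        gm = np.asarray(self.gm)
        if gm.ndim != 4 or gm.shape[1:] != self.grid.dims:
            raise ValueError(
                f"gm must have shape (n,)+{self.grid.dims}, got {gm.shape}"
            )
        if len(self.table) != gm.shape[0]:
            raise CohortShapeError(
                f"{gm.shape[0]} volumes but {len(self.table)} table rows"
            )
        for col in ("id", "group"):
            if col not in self.table.columns:
                raise ValueError(f"subject table lacks required column {col!r}")
        self.gm = gm
        self.table = self.table.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.gm.shape[0]

    @property
    def groups(self) -> list:
        """Group levels in sorted order."""
        return sorted(self.table["group"].unique())

    def has_column(self, name: str) -> bool:
        return name in self.table.columns and not self.table[name].isna().any()

    def masked_data(self, voxels: VoxelSet) -> np.ndarray:
        """Return the (n_subjects, n_voxels) matrix over a voxel set."""
        if not self.grid.matches(voxels.grid):
            raise GridMismatchError("voxel set grid differs from cohort grid")
        return self.gm[:, voxels.mask]

    def with_gm(self, gm: np.ndarray) -> "SubjectCohort":
        """Copy of the cohort with a replaced GM stack (same table/grid)."""
        return SubjectCohort(self.grid, gm, self.table.copy())


def load_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    """Load a 3-D NIfTI volume, returning data and its grid."""
    img = nib.load(str(path))
    grid = VolumeGrid.from_nifti(img)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D volume, got shape {data.shape}")
    return data, grid


def save_volume(data: np.ndarray, grid: VolumeGrid, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), grid.affine)
    img.to_filename(str(path))


def _read_table(table_path) -> pd.DataFrame:
    table = pd.read_csv(table_path, sep="\t")
    for col in ("id", "group"):
        if col not in table.columns:
            raise ValueError(f"subject table {table_path}: missing column {col!r}")
    return table


def load_cohort(volumes, table_path) -> SubjectCohort:
    """Assemble a :class:`SubjectCohort` from disk.

    Parameters
    ----------
    volumes : path or sequence of paths
        Either a single 4-D NIfTI stack (subject as 4th axis) or one 3-D
        NIfTI per subject, ordered as the table rows.
    table_path : path
        TSV with header ``id<TAB>group[<TAB>tbv<TAB>age<TAB>ados_si]``.

    Raises
    ------
    GridMismatchError
        If per-subject volumes do not share one grid (the offending file is
        named in the message).
    CohortShapeError
        If the number of volumes and table rows disagree.
    """
    table = _read_table(table_path)
    if isinstance(volumes, (str, Path)):
        img = nib.load(str(volumes))
        grid = VolumeGrid.from_nifti(img)
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.ndim == 3:
            data = data[..., np.newaxis]
        if data.ndim != 4:
            raise ValueError(f"{volumes}: expected 3-D or 4-D image")
        gm = np.moveaxis(data, -1, 0)
    else:
        paths = list(volumes)
        vols = []
        grid = None
        for p in paths:
            data, g = load_volume(p)
            if grid is None:
                grid = g
            elif not grid.matches(g):
                raise GridMismatchError(
                    f"{p}: grid (dims {g.dims}) differs from first volume "
                    f"(dims {grid.dims})"
                )
            vols.append(data)
        if not vols:
            raise ValueError("no volumes given")
        gm = np.stack(vols, axis=0)
    if gm.shape[0] != len(table):
        raise CohortShapeError(
            f"{gm.shape[0]} volumes but {len(table)} table rows"
        )
    return SubjectCohort(grid=grid, gm=gm, table=table)


def save_cohort(cohort: SubjectCohort, stack_path, table_path) -> None:
    """Write a cohort as a 4-D float32 NIfTI stack and a TSV table."""
    stack = np.moveaxis(cohort.gm, 0, -1).astype(np.float32)
    nib.Nifti1Image(stack, cohort.grid.affine).to_filename(str(stack_path))
    cohort.table.to_csv(table_path, sep="\t", index=False)
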