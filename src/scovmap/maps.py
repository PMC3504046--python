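"""Statistical map containers shared by the GLM and inference layers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_grid import VolumeGrid, VoxelSet, save_volume

__all__ = ["StatMap", "NetworkMask"]


@dataclass
class StatMap:
    """Per-voxel t statistics on an analysis mask.

    ``t`` and the p-value vectors are flat arrays over the member voxels of
    ``mask`` (C order, as returned by :attr:`VoxelSet.indices`).  ``p_unc``
    is the parametric Student-t uncorrected p value under the contrast's
    sidedness; ``p_fwe`` is filled by permutation max-T inference and is
    ``None`` until then.
    """

    grid: VolumeGrid
    mask: VoxelSet
    t: np.ndarray
    df: int
    p_unc: np.ndarray
    side: str
    p_fwe: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.mask)
        for name in ("t", "p_unc", "p_fwe"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")

    def _to_volume(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        vol = np.full(self.grid.dims, fill, dtype=float)
        vol[self.mask.mask] = values
        return vol

    def t_volume(self, fill: float = np.nan) -> np.ndarray:
        return self._to_volume(self.t, fill)

    def p_unc_volume(self, fill: float = np.nan) -> np.ndarray:
        return self._to_volume(self.p_unc, fill)

    def p_fwe_volume(self, fill: float = np.nan) -> np.ndarray:
        if self.p_fwe is None:
            raise ValueError("p_fwe has not been computed for this map")
        return self._to_volume(self.p_fwe, fill)

    def save(self, prefix) -> list:
        """Write t / p_unc (and p_fwe if present) as NIfTI, returning paths."""
        paths = []
        for name, vol in [("t", self.t_volume(0.0)), ("punc", self.p_unc_volume(1.0))]:
            path = f"{prefix}_{name}.nii.gz"
            save_volume(vol, self.grid, path)
            paths.append(path)
        if self.p_fwe is not None:
            path = f"{prefix}_pfwe.nii.gz"
            save_volume(self.p_fwe_volume(1.0), self.grid, path)
            paths.append(path)
        return paths


@dataclass
class NetworkMask:
    """A thresholded (binary) covariance-network map and its provenance."""

    voxels: VoxelSet
    source: str

    def __len__(self) -> int:
        return len(self.voxels)

    def save(self, path) -> None:
        save_volume(self.voxels.mask.astype(np.uint8), self.voxels.grid, path,
                    dtype=np.uint8)
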