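"""Spatial smoothing, analysis-mask construction, and total brain volume.

Voxel-based morphometry statistics are computed on smoothed GM density
maps restricted to an analysis mask.  Smoothing uses a separable Gaussian
kernel specified by its full width at half maximum (FWHM, mm), the field's
conventional parameterization; the default of 12 mm is the level typical
for covariance mapping of low-frequency anatomical structure.  Boundary
handling is zero padding: tissue density is zero outside the head, so no
edge renormalization is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_grid import SubjectCohort, VolumeGrid, VoxelSet

__all__ = [
    "FWHM_TO_SIGMA",
    "AnalysisMask",
    "MaskConfigurationError",
    "fwhm_to_sigma",
    "gaussian_smooth",
    "smooth_cohort",
    "build_analysis_mask",
    "compute_tbv",
    "ensure_tbv",
]

#: Conversion factor between Gaussian FWHM and standard deviation,
#: ``sigma = FWHM / sqrt(8 ln 2)``.
FWHM_TO_SIGMA = 1.0 / float(np.sqrt(8.0 * np.log(2.0)))


class MaskConfigurationError(ValueError):
    """The requested analysis mask is empty."""


@dataclass
class AnalysisMask:
    """Voxels entering the massively univariate GLM, plus how they were chosen."""

    voxels: VoxelSet
    rule: str

    def __len__(self) -> int:
        return len(self.voxels)


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian standard deviation (mm) for a given FWHM (mm)."""
    return float(fwhm_mm) * FWHM_TO_SIGMA


def gaussian_smooth(volume: np.ndarray, grid: VolumeGrid, fwhm_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing of one volume.

    ``sigma`` is converted per-axis to voxel units using the grid's voxel
    size, so anisotropic grids receive an isotropic kernel in mm.  A FWHM
    of 0 returns the input unchanged (as a copy).  Values outside the grid
    are treated as zero.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    volume = np.asarray(volume, dtype=float)
    if volume.shape != grid.dims:
        raise ValueError(f"volume shape {volume.shape} != grid dims {grid.dims}")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_to_sigma(fwhm_mm) / grid.voxel_size
    return ndimage.gaussian_filter(volume, sigma=sigma_vox, mode="constant", cval=0.0)


def smooth_cohort(cohort: SubjectCohort, fwhm_mm: float) -> SubjectCohort:
    """Smooth every subject's GM map; returns a new cohort."""
    if fwhm_mm == 0:
        return cohort.with_gm(cohort.gm.copy())
    out = np.empty_like(cohort.gm, dtype=float)
    for i in range(cohort.n_subjects):
        out[i] = gaussian_smooth(cohort.gm[i], cohort.grid, fwhm_mm)
    return cohort.with_gm(out)


def build_analysis_mask(cohort: SubjectCohort, mean_gm_threshold: float = 0.1) -> AnalysisMask:
    """Mask of voxels whose across-subject mean GM exceeds a threshold.

    This is the conventional VBM implicit mask: it keeps tissue and drops
    background.  The default threshold of 0.1 mean GM density is the usual
    level for modulated segmentations.
    """
    if not 0 <= mean_gm_threshold < 1:
        raise ValueError(
            f"mean_gm_threshold must be in [0, 1), got {mean_gm_threshold}"
        )
    mean_gm = cohort.gm.mean(axis=0)
    mask = mean_gm > mean_gm_threshold
    if not mask.any():
        raise MaskConfigurationError(
            f"analysis mask is empty at mean GM threshold {mean_gm_threshold}"
        )
    return AnalysisMask(
        voxels=VoxelSet(cohort.grid, mask),
        rule=f"mean GM > {mean_gm_threshold}",
    )


def compute_tbv(gm_volume: np.ndarray, grid: VolumeGrid) -> float:
    """Total brain volume (mm^3) from a modulated GM density map.

    Interprets voxel intensity as tissue fraction: TBV is the intensity sum
    times the voxel volume.  Negative intensities (interpolation artifacts)
    are clamped to zero with a warning.
    """
    gm_volume = np.asarray(gm_volume, dtype=float)
    if np.any(gm_volume < 0):
        warnings.warn(
            "negative GM intensities clamped to 0 for TBV", stacklevel=2
        )
        gm_volume = np.clip(gm_volume, 0.0, None)
    return float(gm_volume.sum() * grid.voxel_volume)


def ensure_tbv(cohort: SubjectCohort) -> SubjectCohort:
    """Fill the cohort table's ``tbv`` column where absent.

    A supplied TBV value takes precedence; only missing entries are
    computed from the subject's own GM map.
    """
    table = cohort.table.copy()
    if "tbv" not in table.columns:
        table["tbv"] = np.nan
    missing = table["tbv"].isna()
    for i in np.flatnonzero(missing.to_numpy()):
        table.loc[i, "tbv"] = compute_tbv(cohort.gm[i], cohort.grid)
    return SubjectCohort(cohort.grid, cohort.gm, table)
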