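"""Seed construction and the condition-by-covariate massively univariate GLM.

Structural covariance mapping asks, voxel by voxel, whether GM density
covaries across subjects with the mean GM density inside a small spherical
seed region (or with a behavioral score).  The model is the standard
condition-by-covariate interaction design: per-group intercepts, per-group
slopes for the centered covariate of interest, and shared nuisance
regressors (total brain volume, optionally age).  A within-group covariance
map is a one-sided positive t contrast on that group's slope; a
between-group map contrasts the two slopes head to head.

Estimation is plain per-voxel ordinary least squares with homoscedastic
voxel-wise variance; rows (subjects) are independent by design, so no
whitening is needed.  Columns are internally rescaled to unit norm before
solving, which leaves t statistics unchanged but keeps the normal equations
well conditioned when covariates live on very different scales (e.g. brain
volume in mm^3 next to unit indicators).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_grid import OutsideGridError, SubjectCohort, VolumeGrid, VoxelSet
from .maps import StatMap

__all__ = [
    "T_CAP",
    "SeedSpec",
    "DesignMatrix",
    "Contrast",
    "GlmFit",
    "DesignError",
    "SeedPlacementError",
    "make_sphere_seed",
    "extract_seed_means",
    "build_design",
    "within_group_contrast",
    "between_group_contrast",
    "fit_glm",
    "contrast_t",
]

#: t value reported for voxels with zero residual variance but a nonzero
#: contrast effect (exact linear dependence); preserves ranking without
#: producing infinities.
T_CAP = 1e6

_SIDES = ("greater", "less", "two-sided")


class DesignError(ValueError):
    """The design matrix is invalid (rank deficiency, missing data...)."""


class SeedPlacementError(ValueError):
    """A seed sphere contains no voxels."""


@dataclass(frozen=True)
class SeedSpec:
    """A spherical seed region of interest in world (MNI) coordinates."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.radius_mm < 0:
            raise ValueError(f"radius_mm must be >= 0, got {self.radius_mm}")
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))


def make_sphere_seed(grid: VolumeGrid, seed: SeedSpec) -> VoxelSet:
    """All voxels whose center lies within ``radius_mm`` of the seed center.

    The boundary is inclusive (Euclidean distance in world mm, with a tiny
    relative tolerance so that lattice points exactly on the sphere are kept
    despite float affine arithmetic).
    """
    center = np.asarray(seed.center_mm, dtype=float)
    center_vox = grid.world_to_voxel(center)  # raises OutsideGridError
    if seed.radius_mm == 0:
        return VoxelSet.from_indices(grid, [center_vox])
    # candidate box in voxel space, one voxel of slack per axis
    half = np.ceil(seed.radius_mm / grid.voxel_size).astype(int) + 1
    lo = np.maximum(center_vox - half, 0)
    hi = np.minimum(center_vox + half + 1, np.asarray(grid.dims))
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
    )
    cand = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    d2 = np.sum((grid.voxel_to_world(cand) - center) ** 2, axis=1)
    r2 = seed.radius_mm**2
    inside = cand[d2 <= r2 * (1 + 1e-12) + 1e-9]
    if inside.size == 0:
        raise SeedPlacementError(
            f"seed {seed.name!r} at {seed.center_mm} contains no voxel centers"
        )
    return VoxelSet.from_indices(grid, inside)


def extract_seed_means(cohort: SubjectCohort, voxels: VoxelSet) -> np.ndarray:
    """Per-subject arithmetic mean GM over a voxel set, in table order."""
    if len(voxels) == 0:
        raise ValueError("voxel set is empty")
    return cohort.masked_data(voxels).mean(axis=1)


@dataclass
class DesignMatrix:
    """Named regressors for the condition-by-covariate model.

    ``slope_names`` identifies the covariate-of-interest columns (one per
    group, or a single one without group interaction); covariate and
    nuisance columns are mean-centered over the full sample.
    """

    values: np.ndarray
    names: list[str]
    slope_names: list[str]
    groups: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (n_subjects, n_columns)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass(frozen=True)
class Contrast:
    """A weight vector over design columns plus its sidedness."""

    weights: np.ndarray
    side: str = "greater"
    name: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or not np.any(w):
            raise ValueError("contrast weights must be a non-zero vector")
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")
        w = w.copy()
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)


def _resolve_covariate(cohort: SubjectCohort, covariate, what: str) -> np.ndarray:
    if isinstance(covariate, str):
        if covariate not in cohort.table.columns:
            raise DesignError(f"{what} column {covariate!r} not in subject table")
        values = cohort.table[covariate].to_numpy(dtype=float)
    else:
        values = np.asarray(covariate, dtype=float)
        if values.shape != (cohort.n_subjects,):
            raise DesignError(
                f"{what} must have one value per subject "
                f"({cohort.n_subjects}), got shape {values.shape}"
            )
    if np.any(~np.isfinite(values)):
        bad = cohort.table["id"].iloc[np.flatnonzero(~np.isfinite(values))]
        raise DesignError(f"{what} missing for subjects: {', '.join(map(str, bad))}")
    return values


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    rank = np.linalg.matrix_rank(X)
    involved = []
    for j in range(X.shape[1]):
        rest = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(rest) == rank:
            involved.append(names[j])
    return involved


def build_design(
    cohort: SubjectCohort,
    covariate,
    nuisance: Sequence[str] = ("tbv",),
    group_interaction: bool = True,
) -> DesignMatrix:
    """Build the condition-by-covariate design matrix.

    Parameters
    ----------
    covariate
        The covariate of interest: either a subject-table column name (e.g.
        ``"ados_si"``) or a per-subject vector (e.g. seed means).
    nuisance
        Subject-table columns entered as covariates of no interest.
    group_interaction
        With two groups, fit per-group intercepts and per-group slopes
        (the condition-by-covariate interaction).  Off, a single intercept
        and slope are fit (single-group use).
    """
    s = _resolve_covariate(cohort, covariate, "covariate of interest")
    s_centered = s - s.mean()
    n = cohort.n_subjects

    columns: list[np.ndarray] = []
    names: list[str] = []
    slope_names: list[str] = []
    groups: list = []

    if group_interaction:
        groups = cohort.groups
        if len(groups) != 2:
            raise DesignError(
                f"group interaction requires exactly 2 groups, got {groups}"
            )
        g = cohort.table["group"].to_numpy()
        for level in groups:
            columns.append((g == level).astype(float))
            names.append(f"intercept[{level}]")
        for level in groups:
            columns.append(s_centered * (g == level))
            name = f"slope[{level}]"
            names.append(name)
            slope_names.append(name)
    else:
        columns.append(np.ones(n))
        names.append("intercept")
        columns.append(s_centered)
        names.append("slope")
        slope_names.append("slope")

    for nuis in nuisance:
        v = _resolve_covariate(cohort, nuis, f"nuisance {nuis!r}")
        columns.append(v - v.mean())
        names.append(str(nuis))

    X = np.column_stack(columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(values=X, names=names, slope_names=slope_names, groups=groups)


def within_group_contrast(design: DesignMatrix, group, side: str = "greater") -> Contrast:
    """Contrast selecting one group's covariance slope (the within-group map)."""
    name = f"slope[{group}]" if design.groups else "slope"
    if name not in design.names:
        raise ValueError(f"design has no column {name!r}")
    w = np.zeros(design.n_columns)
    w[design.names.index(name)] = 1.0
    return Contrast(w, side=side, name=f"{group}")


def between_group_contrast(design: DesignMatrix, positive_group, side: str = "greater") -> Contrast:
    """Slope-difference (interaction) contrast, ``positive_group`` minus the other."""
    if len(design.groups) != 2:
        raise ValueError("between-group contrast requires a 2-group design")
    if positive_group not in design.groups:
        raise ValueError(f"{positive_group!r} is not a design group {design.groups}")
    other = [g for g in design.groups if g != positive_group][0]
    w = np.zeros(design.n_columns)
    w[design.names.index(f"slope[{positive_group}]")] = 1.0
    w[design.names.index(f"slope[{other}]")] = -1.0
    return Contrast(w, side=side, name=f"{positive_group}>{other}")


# ---------------------------------------------------------------------------
# OLS core


def _ols_engine(X: np.ndarray):
    """Precompute the pieces of per-voxel OLS for a fixed design.

    Returns ``(solve, df, xtx_inv)`` where ``solve(Y)`` maps an
    ``(n, V)`` data matrix to ``(beta, sigma2)``.
    """
    n, k = X.shape
    norms = np.linalg.norm(X, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    Xs = X / norms
    rank = np.linalg.matrix_rank(Xs)
    df = n - rank
    xtx_inv_s = np.linalg.pinv(Xs.T @ Xs, hermitian=True)
    proj = xtx_inv_s @ Xs.T  # (k, n)
    xtx_inv = xtx_inv_s / np.outer(norms, norms)

    def solve(Y: np.ndarray):
        beta_s = proj @ Y
        resid = Y - Xs @ beta_s
        rss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = rss / df if df > 0 else np.full(Y.shape[1], np.nan)
        beta = beta_s / norms[:, None]
        return beta, sigma2

    return solve, df, xtx_inv


def t_from_effect(effect: np.ndarray, sigma2: np.ndarray, var_c: float) -> np.ndarray:
    """t statistics, capped at ``+-T_CAP`` for (near-)zero-residual voxels."""
    se = np.sqrt(sigma2 * var_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    degenerate = se == 0
    if np.any(degenerate):
        t = np.where(degenerate, np.sign(effect) * T_CAP, t)
    return np.clip(t, -T_CAP, T_CAP)


@dataclass
class GlmFit:
    """Per-voxel OLS estimates over an analysis mask."""

    beta: np.ndarray  # (k, V)
    sigma2: np.ndarray  # (V,)
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray  # (k, k)
    grid: VolumeGrid
    mask: VoxelSet

    @property
    def n_voxels(self) -> int:
        return self.beta.shape[1]


def fit_glm(cohort: SubjectCohort, mask: VoxelSet, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares at every masked voxel.

    Degrees of freedom are ``n_subjects - rank(design)`` and must be >= 1.
    """
    Y = cohort.masked_data(mask)
    n, k = design.values.shape
    if Y.shape[0] != n:
        raise DesignError(f"design has {n} rows but cohort has {Y.shape[0]} subjects")
    solve, df, xtx_inv = _ols_engine(design.values)
    if df < 1:
        raise DesignError(
            f"too few subjects: n={n} with design rank {n - df} leaves df={df}"
        )
    beta, sigma2 = solve(Y)
    return GlmFit(
        beta=beta, sigma2=sigma2, df=df, design=design, xtx_inv=xtx_inv,
        grid=cohort.grid, mask=mask,
    )


def _p_from_t(t: np.ndarray, df: int, side: str) -> np.ndarray:
    if side == "greater":
        p = stats.t.sf(t, df)
    elif side == "less":
        p = stats.t.cdf(t, df)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0)


def contrast_t(fit: GlmFit, contrast: Contrast) -> StatMap:
    """t map and uncorrected p values for a contrast of the fitted model."""
    c = np.asarray(contrast.weights, dtype=float)
    if c.shape != (fit.beta.shape[0],):
        raise ValueError(
            f"contrast length {c.shape} incompatible with design "
            f"({fit.beta.shape[0]} columns)"
        )
    var_c = float(c @ fit.xtx_inv @ c)
    effect = c @ fit.beta
    t = t_from_effect(effect, fit.sigma2, var_c)
    p_unc = _p_from_t(t, fit.df, contrast.side)
    return StatMap(
        grid=fit.grid, mask=fit.mask, t=t, df=fit.df, p_unc=p_unc,
        side=contrast.side,
    )
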