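"""Synthetic cohorts with planted structural-covariance networks.

Real structural covariance arises because GM density at distributed
network nodes rises and falls together across subjects.  The generator
reproduces that statistical structure with the minimal model that yields
seed-to-node covariance: one latent factor per subject loading onto a
group-specific set of spherical network nodes,

    y_i(v) = mu(v) + beta_g(i)(v) * z_i
             + tbv_effect * (TBV_i - mean TBV) * support(v) + eps_i(v),

with ``z_i ~ N(0, 1)``, ``TBV_i`` normal, and ``eps`` spatially smoothed
white noise rescaled so its per-voxel standard deviation equals
``noise_sd`` in the field interior.  A behavioral score (emulating an
observation-schedule social-impairment total) is ``a_g + b * z_i + noise``,
floored at zero.  The phantom is a smooth centered ellipsoid with zero
background; nodes sit at scaled-down analogues of published network peak
coordinates so that they fall inside the phantom.

Everything is deterministic for a fixed ``rng_seed``, and each cohort is
returned together with its ground truth (planted per-group node masks and
their set differences), so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import SeedSpec, make_sphere_seed
from .io_grid import SubjectCohort, VolumeGrid, VoxelSet
from .preprocess import fwhm_to_sigma

__all__ = [
    "NetworkNodeSpec",
    "ScoreModel",
    "CohortSpec",
    "GroundTruth",
    "default_grid",
    "generate_cohort",
    "make_scenario",
    "make_node_atlas",
    "SCENARIOS",
]


def default_grid(dims=(40, 48, 40), voxel_mm: float = 4.0) -> VolumeGrid:
    """Template grid for simulations: 4 mm isotropic, world origin centered.

    The default 40x48x40 grid spans roughly the extent of an adult-template
    bounding box while keeping full-pipeline runs fast.
    """
    dims = tuple(int(d) for d in dims)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -(np.asarray(dims) - 1) / 2.0 * voxel_mm
    return VolumeGrid(dims=dims, affine=affine)


@dataclass(frozen=True)
class NetworkNodeSpec:
    """One spherical network node and its loading on the latent factor.

    ``loading`` is in GM-density units per latent standard deviation: it is
    the covariance amplitude beta(v) planted uniformly inside the node.
    """

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    loading: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"node {self.name!r}: radius must be > 0")
        if not np.isfinite(self.loading):
            raise ValueError(f"node {self.name!r}: loading must be finite")


@dataclass(frozen=True)
class ScoreModel:
    """Behavioral score generated from the latent factor.

    ``intercept`` is per group (scores differ systematically between a
    clinical and a control group); ``slope`` is score units per latent
    standard deviation; scores are floored at zero as real instrument
    totals are non-negative.
    """

    intercept: dict
    slope: float
    noise_sd: float


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of one synthetic two-group cohort."""

    grid: VolumeGrid
    n_per_group: int
    networks: dict  # group label -> tuple of NetworkNodeSpec
    baseline: float = 0.5
    support_semiaxes_mm: tuple[float, float, float] = (60.0, 75.0, 60.0)
    edge_fwhm_mm: float = 6.0
    tbv_mean: float = 1.25e6
    tbv_sd: float = 1.1e5
    tbv_effect: float = 2e-7
    noise_sd: float = 0.08
    noise_fwhm_mm: float = 8.0
    score: ScoreModel = ScoreModel(
        intercept={"A": 0.7, "B": 9.5}, slope=2.0, noise_sd=1.0
    )
    age_mean: float = 13.5
    age_sd: float = 5.2
    rng_seed: int = 0
    seed_node_name: str = "seed"

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError(f"n_per_group must be >= 3, got {self.n_per_group}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        networks = {g: tuple(nodes) for g, nodes in self.networks.items()}
        if len(networks) != 2:
            raise ValueError("networks must specify exactly 2 groups")
        for g, nodes in networks.items():
            if not any(n.name == self.seed_node_name for n in nodes):
                raise ValueError(
                    f"group {g!r} lacks the seed node {self.seed_node_name!r}"
                )
        object.__setattr__(self, "networks", networks)

    @property
    def group_labels(self) -> list:
        return sorted(self.networks)

    def seed_spec(self, radius_mm: float = 4.0) -> SeedSpec:
        """The analysis seed: a small sphere at the planted seed node's center.

        The analysis seed is deliberately smaller (default 4 mm, the
        conventional seed-ROI radius) than the planted anchor node it sits
        in, mirroring how a seed ROI samples the core of a larger
        anatomical structure.
        """
        node = next(
            n for n in self.networks[self.group_labels[0]]
            if n.name == self.seed_node_name
        )
        return SeedSpec(name=node.name, center_mm=node.center_mm,
                        radius_mm=radius_mm)


@dataclass
class GroundTruth:
    """Planted per-group node masks, their differences, and the latent factor."""

    planted: dict  # group -> VoxelSet (union of the group's node spheres)
    differences: dict  # "A_minus_B"-style keys -> VoxelSet
    latent: np.ndarray  # z_i per subject, in table order


def _support_field(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoid indicator and its smoothed (baseline) version."""
    grid = spec.grid
    idx = np.indices(grid.dims).reshape(3, -1).T
    world = grid.voxel_to_world(idx).reshape(*grid.dims, 3)
    semi = np.asarray(spec.support_semiaxes_mm)
    inside = np.sum((world / semi) ** 2, axis=-1) <= 1.0
    baseline = spec.baseline * inside.astype(float)
    if spec.edge_fwhm_mm > 0:
        sigma_vox = fwhm_to_sigma(spec.edge_fwhm_mm) / grid.voxel_size
        baseline = ndimage.gaussian_filter(baseline, sigma=sigma_vox,
                                           mode="constant", cval=0.0)
    return inside, baseline


def _node_mask(grid: VolumeGrid, node: NetworkNodeSpec) -> VoxelSet:
    return make_sphere_seed(
        grid, SeedSpec(node.name, node.center_mm, node.radius_mm)
    )


def _loading_map(spec: CohortSpec, group) -> np.ndarray:
    beta = np.zeros(spec.grid.dims)
    for node in spec.networks[group]:
        beta[_node_mask(spec.grid, node).mask] = node.loading
    return beta


def _smoothed_noise_sd_factor(grid: VolumeGrid, fwhm_mm: float) -> float:
    """Std-dev shrinkage of unit white noise under the discrete Gaussian kernel.

    Mirrors the truncated, normalized kernel used by the smoothing filter
    (truncation at 4 sigma), so rescaling by 1/factor restores an exact
    per-voxel standard deviation in the field interior.
    """
    var = 1.0
    for sigma in fwhm_to_sigma(fwhm_mm) / grid.voxel_size:
        if sigma <= 0:
            continue
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1, dtype=float)
        w = np.exp(-(x**2) / (2.0 * sigma**2))
        w /= w.sum()
        var *= float(np.sum(w**2))
    return float(np.sqrt(var))


def generate_cohort(spec: CohortSpec) -> tuple[SubjectCohort, GroundTruth]:
    """Draw one cohort (GM stack + subject table) and its ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    grid = spec.grid
    groups = spec.group_labels
    n = spec.n_per_group
    n_total = 2 * n

    support, baseline = _support_field(spec)
    loadings = {g: _loading_map(spec, g) for g in groups}

    z = rng.standard_normal(n_total)
    tbv = rng.normal(spec.tbv_mean, spec.tbv_sd, size=n_total)
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n_total), 3.0, 22.0)

    sigma_vox = fwhm_to_sigma(spec.noise_fwhm_mm) / grid.voxel_size
    noise_scale = (
        spec.noise_sd / _smoothed_noise_sd_factor(grid, spec.noise_fwhm_mm)
        if spec.noise_fwhm_mm > 0
        else spec.noise_sd
    )

    gm = np.empty((n_total,) + grid.dims)
    group_col = []
    ids = []
    for i in range(n_total):
        g = groups[i // n]
        group_col.append(g)
        ids.append(f"{g}{i % n + 1:03d}")
        vol = baseline + loadings[g] * z[i]
        vol = vol + spec.tbv_effect * (tbv[i] - spec.tbv_mean) * support
        if spec.noise_sd > 0:
            white = rng.standard_normal(grid.dims)
            if spec.noise_fwhm_mm > 0:
                eps = ndimage.gaussian_filter(white, sigma=sigma_vox,
                                              mode="constant", cval=0.0)
            else:
                eps = white
            vol = vol + noise_scale * eps
        gm[i] = vol

    score_noise = rng.normal(0.0, spec.score.noise_sd, size=n_total)
    score = np.array([
        max(0.0, spec.score.intercept[g] + spec.score.slope * z[i] + score_noise[i])
        for i, g in enumerate(group_col)
    ])

    table = pd.DataFrame({
        "id": ids, "group": group_col, "tbv": tbv, "age": age, "ados_si": score,
    })
    cohort = SubjectCohort(grid=grid, gm=gm, table=table)

    planted = {}
    for g in groups:
        vs = VoxelSet.empty(grid)
        for node in spec.networks[g]:
            vs = vs | _node_mask(grid, node)
        planted[g] = vs
    a, b = groups
    differences = {
        f"{a}_minus_{b}": planted[a] - planted[b],
        f"{b}_minus_{a}": planted[b] - planted[a],
    }
    return cohort, GroundTruth(planted=planted, differences=differences, latent=z)


# ---------------------------------------------------------------------------
# Scenarios
#
# Node centers are published network peak coordinates scaled by 0.75 so the
# spheres sit inside the ellipsoid phantom (semi-axes 60 x 75 x 60 mm).
# Group A plays the control-like role, group B the clinical-like role.

_SCALE = 0.75


def _mni(x: float, y: float, z: float) -> tuple[float, float, float]:
    return (x * _SCALE, y * _SCALE, z * _SCALE)


def _node(name, xyz, radius, loading) -> NetworkNodeSpec:
    return NetworkNodeSpec(name=name, center_mm=_mni(*xyz), radius_mm=radius,
                           loading=loading)


# Network nodes must be resolvable under the analysis smoothing kernel
# (12 mm FWHM): real covariance-network nodes span whole gyri, so full
# nodes get a 12 mm radius (~kernel size) and the seed anchor 8 mm.
_NODE_RADIUS_MM = 12.0
_SEED_NODE_RADIUS_MM = 8.0


def _salience_nodes(loading: float) -> dict:
    """Anterior-network geometry: a frontoinsular seed plus frontal/medial
    nodes for group A; group B keeps only the seed and a residual
    contralateral node (restricted topology)."""
    seed = _node("seed", (38, 26, -10), _SEED_NODE_RADIUS_MM, loading)
    full = (
        seed,
        _node("contra_fi", (-37, 27, -12), _NODE_RADIUS_MM, loading),
        _node("r_sup_frontal", (23, 59, 2), _NODE_RADIUS_MM, loading),
        _node("l_orbitofrontal", (-24, 58, -3), _NODE_RADIUS_MM, loading),
        _node("l_sma", (-15, -11, 58), _NODE_RADIUS_MM, loading),
    )
    restricted = (
        seed,
        _node("contra_fi", (-37, 27, -12), 4.0, loading),
    )
    return {"A": full, "B": restricted}


def _dmn_nodes(loading: float) -> dict:
    """Posterior-network geometry: a posterior-cingulate seed with parietal
    and one anterior node for group A; group B loses the anterior node and
    gains extra posterior nodes (posteriorized topology)."""
    seed = _node("seed", (7, -55, 27), _SEED_NODE_RADIUS_MM, loading)
    shared = (
        seed,
        _node("precuneus", (-8, -53, 45), _NODE_RADIUS_MM, loading),
        _node("r_angular", (40, -58, 40), _NODE_RADIUS_MM, loading),
        _node("l_angular", (-40, -60, 30), _NODE_RADIUS_MM, loading),
    )
    a = shared + (_node("medial_prefrontal", (1, 55, 15), _NODE_RADIUS_MM, loading),)
    b = shared + (
        _node("r_fusiform", (35, -45, -20), _NODE_RADIUS_MM, loading),
        _node("r_mid_occipital", (36, -66, 24), _NODE_RADIUS_MM, loading),
    )
    return {"A": a, "B": b}


def _scenario_restricted_sn() -> CohortSpec:
    return CohortSpec(
        grid=default_grid(), n_per_group=40,
        networks=_salience_nodes(0.15),
        noise_sd=0.08, noise_fwhm_mm=8.0, rng_seed=0,
    )


def _scenario_posteriorized_dmn() -> CohortSpec:
    return CohortSpec(
        grid=default_grid(), n_per_group=40,
        networks=_dmn_nodes(0.15),
        noise_sd=0.08, noise_fwhm_mm=8.0, rng_seed=0,
    )


def _scenario_null() -> CohortSpec:
    """Both groups share the seed node only; the score carries no signal."""
    seed = _node("seed", (38, 26, -10), _SEED_NODE_RADIUS_MM, 0.15)
    return CohortSpec(
        grid=default_grid(), n_per_group=40,
        networks={"A": (seed,), "B": (seed,)},
        noise_sd=0.08, noise_fwhm_mm=8.0,
        score=ScoreModel(intercept={"A": 0.7, "B": 9.5}, slope=0.0, noise_sd=1.0),
        rng_seed=0,
    )


SCENARIOS = {
    "restricted_sn": _scenario_restricted_sn,
    "posteriorized_dmn": _scenario_posteriorized_dmn,
    "null": _scenario_null,
}


def make_scenario(name: str, **overrides) -> CohortSpec:
    """Fully parameterized spec for a named study scenario.

    ``restricted_sn``: group B's planted network is a strict subset of
    group A's (clinical restriction of an anterior network).
    ``posteriorized_dmn``: group B loses an anterior node and gains
    posterior nodes relative to group A.
    ``null``: identical single-node (seed-only) networks and a score with
    zero loading; any off-seed detection is a false positive.

    Keyword overrides are applied to the returned spec (e.g. ``rng_seed``,
    ``n_per_group``) without changing the scenario's geometry.
    """
    try:
        factory = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    spec = factory()
    return replace(spec, **overrides) if overrides else spec


def make_node_atlas(spec: CohortSpec) -> tuple[np.ndarray, dict]:
    """Integer-labeled atlas marking every planted node across both groups.

    Returns the label volume and a ``{label: name}`` mapping; overlapping
    nodes keep the first label assigned.
    """
    atlas = np.zeros(spec.grid.dims, dtype=np.int16)
    names: dict[int, str] = {}
    next_label = 1
    for g in spec.group_labels:
        for node in spec.networks[g]:
            if node.name in names.values():
                continue
            mask = _node_mask(spec.grid, node).mask
            atlas[(atlas == 0) & mask] = next_label
            names[next_label] = node.name
            next_label += 1
    return atlas, names
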