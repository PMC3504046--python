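"""Family-wise error control, thresholding, cluster tables, network extent.

Family-wise error (FWE) across the many voxel-wise tests is controlled by a
permutation max-T procedure: under the Freedman–Lane scheme, residuals from
the nuisance-only model are permuted across subjects, the covariate-of-
interest effect is re-estimated for each permutation, and the maximum
statistic over the mask forms the null.  The corrected p value at voxel v is

    p_fwe(v) = (1 + #{b : maxT_b >= t_v}) / (B + 1),

which is exact under exchangeability of subjects and valid under any
spatial correlation of the data, without estimating map smoothness.

Suprathreshold maps are decomposed into connected clusters (6/18/26
neighborhood), each reported with its size, peak voxel (maximal t, ties
broken by smallest linear index), up to three subsidiary peaks at least
8 mm apart (the conventional reporting rule), and atlas labels when an
integer-labeled atlas is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import (
    Contrast,
    DesignMatrix,
    contrast_t,
    fit_glm,
    t_from_effect,
    _ols_engine,
    _p_from_t,
)
from .io_grid import GridMismatchError, SubjectCohort, VolumeGrid, VoxelSet, save_volume
from .maps import NetworkMask, StatMap

__all__ = [
    "ClusterTable",
    "permutation_max_t",
    "threshold_map",
    "global_network_mask",
    "masked_between_group_map",
    "extract_clusters",
    "label_peaks",
    "count_network_voxels",
    "network_extent_ratio",
]

CLUSTER_TSV_COLUMNS = [
    "cluster_id", "size_vox", "x_mm", "y_mm", "z_mm",
    "peak_t", "peak_p", "primary_label", "secondary_labels",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

#: Minimum world-space separation between reported peaks within a cluster.
SUBPEAK_MIN_DIST_MM = 8.0
SUBPEAKS_PER_CLUSTER = 3


def _oriented(t: np.ndarray, side: str) -> np.ndarray:
    """Statistic whose large values are evidence for the contrast's side."""
    if side == "greater":
        return t
    if side == "less":
        return -t
    return np.abs(t)


def permutation_max_t(
    cohort: SubjectCohort,
    mask: VoxelSet,
    design: DesignMatrix,
    contrast: Contrast,
    n_permutations: int,
    rng_seed,
) -> StatMap:
    """Voxel-wise t map with permutation max-T FWE-corrected p values.

    Freedman–Lane scheme: the columns carrying nonzero contrast weight are
    the exchangeable effect; residuals of the data on the remaining
    (nuisance) columns are permuted across subjects, the full model is
    refit, and the maximum oriented statistic over the mask is recorded per
    permutation.  Deterministic for a fixed ``rng_seed``.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    X = design.values
    c = np.asarray(contrast.weights, dtype=float)
    if c.shape != (X.shape[1],):
        raise ValueError("contrast length does not match design columns")

    Y = cohort.masked_data(mask).astype(float)
    n = Y.shape[0]

    solve, df, xtx_inv = _ols_engine(X)
    var_c = float(c @ xtx_inv @ c)
    beta, sigma2 = solve(Y)
    t_obs = t_from_effect(c @ beta, sigma2, var_c)
    stat_obs = _oriented(t_obs, contrast.side)

    # residualize on the nuisance-only model
    interest = c != 0
    Z = X[:, ~interest]
    if Z.shape[1] > 0:
        gamma, _, _, _ = np.linalg.lstsq(Z, Y, rcond=None)
        resid = Y - Z @ gamma
    else:
        resid = Y

    rng = np.random.default_rng(rng_seed)
    exceed = np.zeros(Y.shape[1], dtype=np.int64)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        beta_b, sigma2_b = solve(resid[perm])
        stat_b = _oriented(t_from_effect(c @ beta_b, sigma2_b, var_c), contrast.side)
        exceed += stat_b.max() >= stat_obs
    p_fwe = (1.0 + exceed) / (n_permutations + 1.0)

    return StatMap(
        grid=cohort.grid, mask=mask, t=t_obs, df=df,
        p_unc=_p_from_t(t_obs, df, contrast.side),
        side=contrast.side, p_fwe=p_fwe,
    )


def threshold_map(statmap: StatMap, alpha: float, use_fwe: bool = True) -> NetworkMask:
    """Binary map of voxels with (corrected or uncorrected) p <= alpha."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if use_fwe:
        if statmap.p_fwe is None:
            raise ValueError("statmap has no p_fwe; run permutation inference first")
        p = statmap.p_fwe
        kind = "FWE"
    else:
        p = statmap.p_unc
        kind = "unc"
    mask = np.zeros(statmap.grid.dims, dtype=bool)
    mask[statmap.mask.mask] = p <= alpha
    return NetworkMask(
        voxels=VoxelSet(statmap.grid, mask),
        source=f"p_{kind} <= {alpha}",
    )


def global_network_mask(
    mask_a: NetworkMask, mask_b: NetworkMask, mode: str = "union"
) -> NetworkMask:
    """Combine the two groups' thresholded maps into the network global map.

    ``union`` (default) keeps voxels significant in either group;
    ``conjunction`` keeps voxels significant in both.
    """
    if mode == "union":
        voxels = mask_a.voxels | mask_b.voxels
    elif mode == "conjunction":
        voxels = mask_a.voxels & mask_b.voxels
    else:
        raise ValueError(f"mode must be 'union' or 'conjunction', got {mode!r}")
    return NetworkMask(
        voxels=voxels, source=f"{mode}({mask_a.source}; {mask_b.source})"
    )


def masked_between_group_map(
    statmap_diff: StatMap, global_mask: NetworkMask, alpha_unc: float = 0.05
) -> NetworkMask:
    """Between-group difference voxels (uncorrected p) inside the global map.

    The result is by construction a subset of ``global_mask``.
    """
    unc = threshold_map(statmap_diff, alpha_unc, use_fwe=False)
    voxels = unc.voxels & global_mask.voxels
    return NetworkMask(
        voxels=voxels,
        source=f"p_unc <= {alpha_unc} within {global_mask.source}",
    )


@dataclass
class ClusterTable:
    """Suprathreshold clusters with peaks, plus the cluster-label volume."""

    table: pd.DataFrame
    labels: np.ndarray  # int volume, 0 = background
    grid: VolumeGrid

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False,
                          columns=[c for c in CLUSTER_TSV_COLUMNS
                                   if c in self.table.columns])


def _cluster_peaks(t_vol, member_idx, grid):
    """Primary peak plus subsidiary peaks >= 8 mm apart (up to 3 extra)."""
    tvals = t_vol[tuple(member_idx.T)]
    # stable sort, descending t; ties resolved by C-order linear index
    order = np.argsort(-tvals, kind="stable")
    world = grid.voxel_to_world(member_idx)
    chosen: list[int] = []
    for j in order:
        if not chosen:
            chosen.append(j)
            continue
        if len(chosen) > SUBPEAKS_PER_CLUSTER:
            break
        d = np.linalg.norm(world[chosen] - world[j], axis=1)
        if np.all(d >= SUBPEAK_MIN_DIST_MM):
            chosen.append(j)
    return member_idx[chosen], tvals[chosen]


def extract_clusters(
    network_mask: NetworkMask,
    statmap: StatMap,
    connectivity: int = 26,
) -> ClusterTable:
    """Connected components of a binary network map, with peak statistics.

    Clusters are ordered by descending peak t; cluster sizes partition the
    mask.  ``peak_p`` is the FWE-corrected p at the peak when available,
    otherwise the uncorrected p.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {set(_CONNECTIVITY_RANK)}")
    grid = network_mask.voxels.grid
    if not grid.matches(statmap.grid):
        raise GridMismatchError("network mask and stat map are on different grids")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_clusters = ndimage.label(network_mask.voxels.mask, structure=structure)

    t_vol = statmap.t_volume(fill=-np.inf)
    p_vol = (statmap.p_fwe_volume(1.0) if statmap.p_fwe is not None
             else statmap.p_unc_volume(1.0))

    rows = []
    for lab in range(1, n_clusters + 1):
        member_idx = np.argwhere(labels == lab)
        peaks_idx, peaks_t = _cluster_peaks(t_vol, member_idx, grid)
        peak = peaks_idx[0]
        peak_mm = grid.voxel_to_world(peak)
        sub = [
            (grid.voxel_to_world(ix).tolist(), float(tv))
            for ix, tv in zip(peaks_idx[1:], peaks_t[1:])
        ]
        rows.append({
            "size_vox": int(member_idx.shape[0]),
            "x_mm": float(peak_mm[0]),
            "y_mm": float(peak_mm[1]),
            "z_mm": float(peak_mm[2]),
            "peak_t": float(peaks_t[0]),
            "peak_p": float(p_vol[tuple(peak)]),
            "primary_label": "",
            "secondary_labels": "",
            "subsidiary_peaks": sub,
            "_label": lab,
        })
    rows.sort(key=lambda r: -r["peak_t"])
    relabel = np.zeros(n_clusters + 1, dtype=int)
    for new_id, row in enumerate(rows, start=1):
        relabel[row.pop("_label")] = new_id
        row["cluster_id"] = new_id
    table = pd.DataFrame(
        rows,
        columns=["cluster_id", "size_vox", "x_mm", "y_mm", "z_mm", "peak_t",
                 "peak_p", "primary_label", "secondary_labels",
                 "subsidiary_peaks"],
    )
    return ClusterTable(table=table, labels=relabel[labels], grid=grid)


def label_peaks(
    clusters: ClusterTable,
    atlas_volume: np.ndarray,
    atlas_names: dict,
    max_secondary: int = 3,
) -> ClusterTable:
    """Fill primary/secondary atlas labels into a cluster table.

    The primary label is the atlas region at the peak voxel (background 0
    maps to ``"unlabeled"``); secondary labels are the other regions the
    cluster overlaps, ordered by descending voxel overlap.
    """
    atlas = np.asarray(atlas_volume)
    if atlas.shape != clusters.grid.dims:
        raise GridMismatchError(
            f"atlas shape {atlas.shape} does not match grid dims {clusters.grid.dims}"
        )
    names = {int(k): str(v) for k, v in atlas_names.items()}

    table = clusters.table.copy()
    for i, row in table.iterrows():
        cid = int(row["cluster_id"])
        member = clusters.labels == cid
        peak_idx = clusters.grid.world_to_voxel(
            [row["x_mm"], row["y_mm"], row["z_mm"]]
        )
        peak_val = int(atlas[tuple(peak_idx)])
        primary = names.get(peak_val, "unlabeled") if peak_val != 0 else "unlabeled"
        overlap_vals, overlap_counts = np.unique(atlas[member], return_counts=True)
        secondary = [
            (names.get(int(v), f"region{int(v)}"), int(cnt))
            for v, cnt in zip(overlap_vals, overlap_counts)
            if int(v) != 0 and int(v) != peak_val
        ]
        secondary.sort(key=lambda item: -item[1])
        table.loc[i, "primary_label"] = primary
        table.loc[i, "secondary_labels"] = ";".join(
            name for name, _ in secondary[:max_secondary]
        )
    return replace(clusters, table=table)


def count_network_voxels(network_mask: NetworkMask) -> int:
    """Total number of significant voxels in a network map."""
    return len(network_mask.voxels)


def network_extent_ratio(mask_a: NetworkMask, mask_b: NetworkMask) -> float:
    """Voxel-count ratio |A| / |B| between two network maps."""
    nb = count_network_voxels(mask_b)
    if nb == 0:
        raise ZeroDivisionError("denominator network map is empty")
    return count_network_voxels(mask_a) / nb
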