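import numpy as np
import pytest

from scovmap.glm import (
    Contrast,
    build_design,
    contrast_t,
    fit_glm,
    within_group_contrast,
)
from scovmap.inference import (
    count_network_voxels,
    extract_clusters,
    global_network_mask,
    label_peaks,
    masked_between_group_map,
    network_extent_ratio,
    permutation_max_t,
    threshold_map,
)
from scovmap.io_grid import VolumeGrid, VoxelSet
from scovmap.maps import NetworkMask, StatMap

from conftest import make_cohort


def _flat_statmap(grid, t_vol, mask_vol, df=20, p_fwe=None, side="greater"):
    """StatMap from full volumes (test helper)."""
    from scipy import stats

    mask = VoxelSet(grid, mask_vol)
    t = t_vol[mask_vol]
    p_unc = np.clip(stats.t.sf(t, df), np.finfo(float).tiny, 1.0)
    return StatMap(grid=grid, mask=mask, t=t, df=df, p_unc=p_unc,
                   side=side, p_fwe=p_fwe)


@pytest.fixture
def null_perm_map(mm4_grid):
    """Permutation run on pure-noise data with one planted strong voxel."""
    rng = np.random.default_rng(42)
    n = 16
    gm = 0.05 * rng.standard_normal((n,) + mm4_grid.dims)
    cov = rng.standard_normal(n)
    # plant an exact covariate effect at one voxel
    gm[:, 10, 10, 10] += 1.0 * cov
    cohort = make_cohort(mm4_grid, gm, ["A"] * 8 + ["B"] * 8,
                         tbv=rng.normal(1e6, 1e5, n))
    design = build_design(cohort, cov, nuisance=("tbv",))
    mask = VoxelSet(mm4_grid, np.ones(mm4_grid.dims, dtype=bool))
    contrast = within_group_contrast(design, "A")
    sm = permutation_max_t(cohort, mask, design, contrast,
                           n_permutations=99, rng_seed=7)
    return cohort, mask, design, contrast, sm


class TestPermutationMaxT:
    def test_minimum_attainable_p(self, null_perm_map):
        _, _, _, _, sm = null_perm_map
        assert sm.p_fwe.min() >= 1.0 / 100.0 - 1e-12
        # the planted voxel beats every permutation maximum
        planted = np.ravel_multi_index((10, 10, 10), sm.grid.dims)
        flat_idx = np.flatnonzero(sm.mask.mask.ravel())
        assert sm.p_fwe[np.searchsorted(flat_idx, planted)] == pytest.approx(0.01)

    def test_fwe_dominates_uncorrected(self, null_perm_map):
        _, _, _, _, sm = null_perm_map
        assert np.all(sm.p_fwe >= sm.p_unc - 1e-12)

    def test_deterministic_for_fixed_seed(self, null_perm_map):
        cohort, mask, design, contrast, sm = null_perm_map
        sm2 = permutation_max_t(cohort, mask, design, contrast,
                                n_permutations=99, rng_seed=7)
        assert np.array_equal(sm.p_fwe, sm2.p_fwe)
        assert np.array_equal(sm.t, sm2.t)

    def test_invalid_permutation_count(self, null_perm_map):
        cohort, mask, design, contrast, _ = null_perm_map
        with pytest.raises(ValueError, match=">= 1"):
            permutation_max_t(cohort, mask, design, contrast, 0, 1)


class TestThresholding:
    def test_monotone_in_alpha(self, null_perm_map):
        _, _, _, _, sm = null_perm_map
        masks = [threshold_map(sm, a, use_fwe=True).voxels
                 for a in (0.01, 0.05, 0.2)]
        assert masks[0].issubset(masks[1])
        assert masks[1].issubset(masks[2])

    def test_alpha_below_minimum_gives_empty_mask(self, null_perm_map):
        _, _, _, _, sm = null_perm_map
        assert len(threshold_map(sm, 0.005, use_fwe=True).voxels) == 0

    def test_all_significant_toy_map(self, mm4_grid):
        t_vol = np.full(mm4_grid.dims, 10.0)
        mask_vol = np.ones(mm4_grid.dims, dtype=bool)
        sm = _flat_statmap(mm4_grid, t_vol, mask_vol)
        assert len(threshold_map(sm, 0.05, use_fwe=False).voxels) == mm4_grid.n_voxels


class TestGlobalMask:
    def _mask(self, grid, idx):
        return NetworkMask(VoxelSet.from_indices(grid, idx), source="x")

    def test_union_of_disjoint(self, unit_grid):
        a = self._mask(unit_grid, [[i, 0, 0] for i in range(5)])
        b = self._mask(unit_grid, [[i, 1, 0] for i in range(3)])
        assert len(global_network_mask(a, b).voxels) == 8

    def test_idempotent_and_empty_identity(self, unit_grid):
        m = self._mask(unit_grid, [[1, 1, 1], [2, 2, 2]])
        empty = NetworkMask(VoxelSet.empty(unit_grid), source="0")
        assert global_network_mask(m, m).voxels == m.voxels
        assert global_network_mask(empty, m).voxels == m.voxels

    def test_conjunction_mode(self, unit_grid):
        a = self._mask(unit_grid, [[0, 0, 0], [1, 1, 1]])
        b = self._mask(unit_grid, [[1, 1, 1], [2, 2, 2]])
        conj = global_network_mask(a, b, mode="conjunction")
        assert conj.voxels.indices.tolist() == [[1, 1, 1]]


class TestMaskedBetweenGroupMap:
    def test_subset_of_global_mask(self, mm4_grid):
        rng = np.random.default_rng(3)
        t_vol = rng.standard_normal(mm4_grid.dims) * 3
        mask_vol = np.ones(mm4_grid.dims, dtype=bool)
        sm = _flat_statmap(mm4_grid, t_vol, mask_vol)
        gmask = NetworkMask(
            VoxelSet.from_indices(mm4_grid, [[i, j, 5] for i in range(5)
                                             for j in range(5)]),
            source="global",
        )
        out = masked_between_group_map(sm, gmask, alpha_unc=0.5)
        assert out.voxels.issubset(gmask.voxels)

    def test_empty_global_mask_gives_empty_result(self, mm4_grid):
        t_vol = np.full(mm4_grid.dims, 10.0)
        sm = _flat_statmap(mm4_grid, t_vol, np.ones(mm4_grid.dims, bool))
        empty = NetworkMask(VoxelSet.empty(mm4_grid), source="0")
        assert len(masked_between_group_map(sm, empty, 0.05)) == 0


class TestClusters:
    def test_two_separated_blobs(self, unit_grid):
        mask_vol = np.zeros(unit_grid.dims, dtype=bool)
        mask_vol[0:2, 0:2, 0:2] = True
        mask_vol[5:7, 5:7, 5:7] = True
        t_vol = np.where(mask_vol, 5.0, 0.0)
        t_vol[1, 1, 1] = 9.0
        sm = _flat_statmap(unit_grid, t_vol, mask_vol)
        ct = extract_clusters(NetworkMask(VoxelSet(unit_grid, mask_vol), "x"),
                              sm, connectivity=26)
        assert len(ct.table) == 2
        # partition: sizes sum to mask cardinality
        assert ct.table["size_vox"].sum() == mask_vol.sum()
        # clusters ordered by peak t; peak lies inside its cluster
        assert ct.table.loc[0, "peak_t"] == 9.0
        assert ct.labels[1, 1, 1] == 1

    @pytest.mark.parametrize("connectivity,n_expected", [(6, 2), (18, 2), (26, 1)])
    def test_corner_touch_connectivity(self, unit_grid, connectivity, n_expected):
        mask_vol = np.zeros(unit_grid.dims, dtype=bool)
        mask_vol[2, 2, 2] = True
        mask_vol[3, 3, 3] = True  # touches only at a corner
        t_vol = np.where(mask_vol, 4.0, 0.0)
        sm = _flat_statmap(unit_grid, t_vol, mask_vol)
        ct = extract_clusters(NetworkMask(VoxelSet(unit_grid, mask_vol), "x"),
                              sm, connectivity=connectivity)
        assert len(ct.table) == n_expected

    def test_single_voxel_cluster(self, unit_grid):
        mask_vol = np.zeros(unit_grid.dims, dtype=bool)
        mask_vol[4, 4, 4] = True
        t_vol = np.where(mask_vol, 3.3, 0.0)
        sm = _flat_statmap(unit_grid, t_vol, mask_vol)
        ct = extract_clusters(NetworkMask(VoxelSet(unit_grid, mask_vol), "x"), sm)
        assert len(ct.table) == 1
        assert ct.table.loc[0, "size_vox"] == 1
        assert tuple(unit_grid.world_to_voxel(
            ct.table.loc[0, ["x_mm", "y_mm", "z_mm"]].to_numpy()
        )) == (4, 4, 4)

    def test_subsidiary_peaks_respect_min_distance(self):
        grid = VolumeGrid(dims=(30, 5, 5), affine=np.eye(4))
        mask_vol = np.zeros(grid.dims, dtype=bool)
        mask_vol[0:25, 2, 2] = True
        t_vol = np.zeros(grid.dims)
        t_vol[0:25, 2, 2] = 1.0
        t_vol[2, 2, 2] = 8.0   # primary
        t_vol[6, 2, 2] = 7.0   # 4 mm away: suppressed
        t_vol[14, 2, 2] = 6.0  # 12 mm away: subsidiary
        sm = _flat_statmap(grid, t_vol, mask_vol)
        ct = extract_clusters(NetworkMask(VoxelSet(grid, mask_vol), "x"), sm)
        subs = ct.table.loc[0, "subsidiary_peaks"]
        sub_x = [p[0][0] for p in subs]
        assert ct.table.loc[0, "x_mm"] == 2.0
        assert 14.0 in sub_x and 6.0 not in sub_x


class TestLabelPeaks:
    def _clusters(self, unit_grid):
        mask_vol = np.zeros(unit_grid.dims, dtype=bool)
        mask_vol[0:2, 0:5, 0] = True  # 10-voxel cluster
        t_vol = np.where(mask_vol, 2.0, 0.0)
        t_vol[0, 0, 0] = 5.0
        sm = _flat_statmap(unit_grid, t_vol, mask_vol)
        return extract_clusters(NetworkMask(VoxelSet(unit_grid, mask_vol), "x"), sm)

    def test_primary_label_lookup(self, unit_grid):
        ct = self._clusters(unit_grid)
        atlas = np.zeros(unit_grid.dims, dtype=int)
        atlas[0:2, 0:5, 0] = 3
        out = label_peaks(ct, atlas, {3: "regionC"})
        assert out.table.loc[0, "primary_label"] == "regionC"

    def test_background_peak_is_unlabeled(self, unit_grid):
        ct = self._clusters(unit_grid)
        atlas = np.zeros(unit_grid.dims, dtype=int)
        out = label_peaks(ct, atlas, {})
        assert out.table.loc[0, "primary_label"] == "unlabeled"

    def test_secondary_ordered_by_overlap(self, unit_grid):
        ct = self._clusters(unit_grid)
        atlas = np.zeros(unit_grid.dims, dtype=int)
        atlas[0, 0, 0] = 3          # peak region
        atlas[0:2, 1:4, 0] = 1      # region1 overlap: 6 voxels
        atlas[0:2, 4:5, 0] = 2      # region2 overlap: 2 voxels (and 1 voxel of 1 left)
        atlas[1, 0, 0] = 1          # region1: 7 voxels total
        out = label_peaks(ct, atlas, {1: "region1", 2: "region2", 3: "regionC"})
        assert out.table.loc[0, "secondary_labels"].split(";")[:2] == [
            "region1", "region2",
        ]

    def test_atlas_grid_mismatch(self, unit_grid):
        ct = self._clusters(unit_grid)
        with pytest.raises(Exception, match="atlas"):
            label_peaks(ct, np.zeros((3, 3, 3), dtype=int), {})


class TestCounts:
    def test_counts_and_ratio(self, unit_grid):
        a = NetworkMask(VoxelSet.from_indices(
            unit_grid, [[i, j, 0] for i in range(2) for j in range(4)]), "a")
        b = NetworkMask(VoxelSet.from_indices(
            unit_grid, [[i, j, k] for i in range(5) for j in range(5)
                        for k in range(4)]), "b")
        empty = NetworkMask(VoxelSet.empty(unit_grid), "0")
        assert count_network_voxels(empty) == 0
        assert count_network_voxels(a) == 8
        assert count_network_voxels(b) == 100
        assert network_extent_ratio(a, b) == pytest.approx(0.08)
        with pytest.raises(ZeroDivisionError):
            network_extent_ratio(a, empty)
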