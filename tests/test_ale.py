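import numpy as np
import pytest
from scipy import stats

import metaconn as mc
from metaconn.ale import (cluster_extent_fwe_threshold,
                          extract_clusters)
from metaconn.kernels import build_kernel

from conftest import random_ma_maps


class TestUnion:
    def test_two_values_union(self, full_grid_10):
        a = np.zeros(full_grid_10.shape)
        b = np.zeros(full_grid_10.shape)
        a[3, 3, 3], b[3, 3, 3] = 0.2, 0.5
        out = mc.ale_union([mc.VolumeMap(full_grid_10, a, "MA"),
                            mc.VolumeMap(full_grid_10, b, "MA")])
        assert out.data[3, 3, 3] == pytest.approx(0.6, abs=1e-12)

    def test_all_zero_maps_give_zero(self, full_grid_10):
        maps = [mc.VolumeMap(full_grid_10, np.zeros(full_grid_10.shape), "MA")
                for _ in range(3)]
        assert np.all(mc.ale_union(maps).data == 0)

    def test_matches_brute_force_product_loop(self, full_grid_10):
        rng = np.random.default_rng(3)
        maps = random_ma_maps(full_grid_10, 5, rng)
        out = mc.ale_union(maps)
        # brute-force per-voxel loop oracle
        expected = np.empty(full_grid_10.shape)
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    prod = 1.0
                    for m in maps:
                        prod *= 1.0 - m.data[i, j, k]
                    expected[i, j, k] = 1.0 - prod
        assert np.abs(out.data - expected).max() < 1e-12

    def test_dominates_each_ma_and_ignores_zero_map(self, full_grid_10):
        rng = np.random.default_rng(4)
        maps = random_ma_maps(full_grid_10, 4, rng)
        out = mc.ale_union(maps)
        for m in maps:
            assert np.all(out.data >= m.data - 1e-15)
        with_zero = maps + [mc.VolumeMap(full_grid_10,
                                         np.zeros(full_grid_10.shape), "MA")]
        assert np.allclose(mc.ale_union(with_zero).data, out.data)

    def test_grid_mismatch_rejected(self, full_grid_10, small_grid):
        a = mc.VolumeMap(full_grid_10, np.zeros(full_grid_10.shape), "MA")
        b = mc.VolumeMap(small_grid, np.zeros(small_grid.shape), "MA")
        with pytest.raises(Exception, match="mismatch"):
            mc.ale_union([a, b])


@pytest.fixture(scope="module")
def toy_null():
    """2 experiments on a <=100-voxel toy grid, plus its exact null."""
    grid = mc.make_grid(10.0, (40.0, 50.0, 50.0), "full")  # 4*5*5 = 100 voxels
    rng = np.random.default_rng(12)
    maps = random_ma_maps(grid, 2, rng, scale=0.3)
    null = mc.ale_null_histogram(maps, grid, bin_width=1e-5)
    return grid, maps, null


class TestNullHistogram:
    def test_single_experiment_null_is_its_histogram(self, full_grid_10):
        rng = np.random.default_rng(6)
        m = random_ma_maps(full_grid_10, 1, rng)[0]
        null = mc.ale_null_histogram([m], full_grid_10, bin_width=1e-5)
        vals = m.masked_values
        idx = np.floor(vals / 1e-5 + 1e-9).astype(int)
        expected = np.bincount(idx, minlength=len(null.null_pmf)) / len(vals)
        assert np.allclose(null.null_pmf, expected, atol=1e-12)

    def test_pmf_sums_to_one(self, toy_null):
        _, _, null = toy_null
        assert null.null_pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_cdf_matches_monte_carlo_resampling(self, toy_null):
        grid, maps, null = toy_null
        # independent Monte-Carlo oracle: union of each experiment's MA at
        # independently drawn random in-mask voxels
        rng = np.random.default_rng(99)
        n_draw = 200_000
        vals = [m.masked_values for m in maps]
        draws = 1.0 - (1.0 - vals[0][rng.integers(0, len(vals[0]), n_draw)]) * (
            1.0 - vals[1][rng.integers(0, len(vals[1]), n_draw)]
        )
        q95 = np.quantile(draws, 0.95)
        p_exact = null.p_of(np.array([q95]))[0]
        p_mc = (draws >= q95).mean()
        assert abs(p_exact - p_mc) <= 0.005

    def test_empty_map_list_rejected(self, full_grid_10):
        with pytest.raises(ValueError):
            mc.ale_null_histogram([], full_grid_10)


class TestVoxelPvalues:
    def test_zero_observation_has_p_one(self, toy_null):
        grid, maps, null = toy_null
        ale = mc.VolumeMap(grid, np.zeros(grid.shape), "ALE")
        p, z = mc.voxel_pvalues(ale, null)
        assert np.all(p.masked_values == 1.0)
        assert np.all(z.masked_values <= 0)

    def test_null_median_maps_to_half(self, toy_null):
        grid, maps, null = toy_null
        cdf = np.cumsum(null.null_pmf)
        med_bin = int(np.searchsorted(cdf, 0.5))
        p = null.p_of(np.array([med_bin * null.bin_width]))[0]
        assert 0.4 < p < 0.6

    def test_pvalues_uniform_under_resampling_null(self, toy_null):
        # draw ALE values from the null itself; with continuous MA values
        # the resulting p-values must be uniform (KS not rejecting at 0.01)
        grid, maps, null = toy_null
        rng = np.random.default_rng(17)
        vals = [m.masked_values for m in maps]
        draws = 1.0 - (1.0 - vals[0][rng.integers(0, len(vals[0]), 10_000)]) * (
            1.0 - vals[1][rng.integers(0, len(vals[1]), 10_000)]
        )
        p = null.p_of(draws)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_above_support_assigned_smallest_tail(self, toy_null):
        grid, maps, null = toy_null
        p = null.p_of(np.array([1.0]))
        assert p[0] == null.survival[null.survival > 0].min()


class TestClusters:
    def test_cube_volume_arithmetic(self):
        grid = mc.make_grid(2.0, 20.0, "full")
        t = np.zeros(grid.shape, dtype=bool)
        t[2:4, 2:4, 2:4] = True
        df = extract_clusters(t, grid)
        assert len(df) == 1
        assert df.volume_mm3.iloc[0] == pytest.approx(64.0)

    def test_corner_touching_blobs_are_one_cluster(self):
        grid = mc.make_grid(2.0, 20.0, "full")
        t = np.zeros(grid.shape, dtype=bool)
        t[2, 2, 2] = True
        t[3, 3, 3] = True  # touches only at a corner
        assert len(extract_clusters(t, grid)) == 1

    def test_empty_map_yields_empty_table(self, small_grid):
        df = extract_clusters(np.zeros(small_grid.shape, bool), small_grid)
        assert len(df) == 0

    def test_matches_brute_force_flood_fill(self, small_grid):
        rng = np.random.default_rng(8)
        t = (rng.random(small_grid.shape) < 0.08) & small_grid.mask
        df = extract_clusters(t, small_grid)
        # brute-force 26-connectivity flood fill oracle
        seen = np.zeros(small_grid.shape, bool)
        sizes = []
        for start in np.argwhere(t):
            s = tuple(start)
            if seen[s]:
                continue
            stack, size = [s], 0
            seen[s] = True
            while stack:
                cur = stack.pop()
                size += 1
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            nb = (cur[0] + di, cur[1] + dj, cur[2] + dk)
                            if all(0 <= nb[a] < small_grid.shape[a]
                                   for a in range(3)) and t[nb] and not seen[nb]:
                                seen[nb] = True
                                stack.append(nb)
            sizes.append(size)
        assert sorted(df.n_voxels) == sorted(sizes)


class TestExtentFwe:
    def _experiments(self, grid, n_exp=6, n_foci=4):
        k = build_kernel(10.0, grid)
        return [(n_foci, k)] * n_exp

    def test_recorded_maxima_bookkeeping(self, small_grid):
        thr, maxima = cluster_extent_fwe_threshold(
            self._experiments(small_grid), small_grid, ale_cutoff=0.05,
            n_iterations=50, seed=1)
        assert len(maxima) == 50

    def test_same_seed_reproduces_threshold(self, small_grid):
        a = cluster_extent_fwe_threshold(self._experiments(small_grid),
                                         small_grid, 0.05, 60, seed=9)
        b = cluster_extent_fwe_threshold(self._experiments(small_grid),
                                         small_grid, 0.05, 60, seed=9)
        assert a[0] == b[0] and a[1] == b[1]

    def test_seed_required(self, small_grid):
        with pytest.raises(ValueError, match="seed"):
            cluster_extent_fwe_threshold(self._experiments(small_grid),
                                         small_grid, 0.05, 10, seed=None)


class TestConjunction:
    def test_idempotent_on_identical_inputs(self, full_grid_10):
        rng = np.random.default_rng(10)
        m = random_ma_maps(full_grid_10, 1, rng)[0]
        t = m.data > 0.05
        out = mc.conjunction(t, t, m, m)
        assert np.allclose(out.data[t], m.data[t])
        assert np.all(out.data[~t] == 0)

    def test_disjoint_sets_empty(self, full_grid_10):
        m = mc.VolumeMap(full_grid_10, np.full(full_grid_10.shape, 0.3), "ALE")
        ta = np.zeros(full_grid_10.shape, bool)
        tb = np.zeros(full_grid_10.shape, bool)
        ta[0, 0, 0] = True
        tb[5, 5, 5] = True
        assert np.all(mc.conjunction(ta, tb, m, m).data == 0)

    def test_bounded_by_min_of_inputs(self, full_grid_10):
        rng = np.random.default_rng(11)
        a, b = random_ma_maps(full_grid_10, 2, rng, scale=0.5)
        a = mc.VolumeMap(full_grid_10, a.data, "ALE")
        b = mc.VolumeMap(full_grid_10, b.data, "ALE")
        out = mc.conjunction(a.data > 0.1, b.data > 0.1, a, b)
        assert np.all(out.data <= np.minimum(a.data, b.data) + 1e-15)
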