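import numpy as np
import pytest

import metaconn as mc
from metaconn.rsfc import RestRun


def _run(grid, series, subject="sub01", run_id="run1"):
    return RestRun(grid=grid, series=series, tr_seconds=1.0,
                   subject_id=subject, run_id=run_id)


@pytest.fixture(scope="module")
def one_voxel_roi(small_grid):
    return mc.sphere_roi(small_grid.voxel_to_world([9, 9, 8]), 1.0,
                         small_grid, roi_id="r1")


class TestSeedTimecourse:
    def test_single_voxel_roi_returns_its_series(self, small_grid,
                                                 one_voxel_roi):
        rng = np.random.default_rng(0)
        series = rng.standard_normal(small_grid.shape + (30,))
        run = _run(small_grid, series)
        vox = tuple(one_voxel_roi.voxels[0])
        assert np.array_equal(mc.seed_timecourse(run, one_voxel_roi),
                              series[vox])

    def test_opposite_series_cancel(self, small_grid):
        roi = mc.sphere_roi(small_grid.voxel_to_world([9, 9, 8]), 4.5,
                            small_grid)
        assert roi.n_voxels >= 2
        series = np.zeros(small_grid.shape + (30,))
        s = np.sin(np.arange(30))
        v0, v1 = roi.voxels[0], roi.voxels[1]
        series[tuple(v0)] = s
        series[tuple(v1)] = -s
        tc = mc.seed_timecourse(_run(small_grid, series),
                                mc.SeedROI("r", roi.center_mm, 6.0,
                                           np.vstack([v0, v1])))
        assert np.abs(tc).max() < 1e-12

    def test_matches_brute_force_mean(self, small_grid):
        roi = mc.sphere_roi(small_grid.voxel_to_world([8, 9, 8]), 6.0,
                            small_grid)
        rng = np.random.default_rng(1)
        series = rng.standard_normal(small_grid.shape + (25,))
        run = _run(small_grid, series)
        got = mc.seed_timecourse(run, roi)
        expected = np.zeros(25)
        for v in roi.voxels:
            expected += series[tuple(v)]
        expected /= len(roi.voxels)
        assert np.allclose(got, expected, atol=1e-12)


class TestSeedConnectivity:
    def test_perfect_coupling_scores_one(self, small_grid, one_voxel_roi):
        rng = np.random.default_rng(2)
        T = 60
        seed_series = rng.standard_normal(T)
        series = np.zeros(small_grid.shape + (T,))
        series[tuple(one_voxel_roi.voxels[0])] = seed_series
        target = (5, 5, 5)
        series[target] = seed_series  # perfectly coupled voxel
        series[5, 5, 6] = -2.0 * seed_series  # keeps the global signal zero
        m = mc.seed_connectivity(_run(small_grid, series), one_voxel_roi,
                                 smoothing_fwhm=0.0)
        assert m.beta_map.data[target] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_scores_near_zero(self, small_grid,
                                                one_voxel_roi):
        rng = np.random.default_rng(3)
        T = 200
        series = rng.standard_normal(small_grid.shape + (T,))
        m = mc.seed_connectivity(_run(small_grid, series), one_voxel_roi,
                                 smoothing_fwhm=0.0)
        others = ~one_voxel_roi.mask_array(small_grid) & small_grid.mask
        # sampling bound at T=200 (|r| < 0.2 except vanishing tail)
        assert np.quantile(np.abs(m.beta_map.data[others]), 0.99) < 0.2

    def test_global_signal_absorbed_by_nuisance(self, small_grid,
                                                one_voxel_roi):
        rng = np.random.default_rng(4)
        T = 80
        g = rng.standard_normal(T)
        seed_series = rng.standard_normal(T)
        series = np.tile(g, small_grid.shape + (1,)).astype(float)
        sv = tuple(one_voxel_roi.voxels[0])
        series[sv] = seed_series + 0.1 * g
        series[5, 5, 6] = g - (series[sv] - g)  # keeps the global mean at g
        target = (5, 5, 5)  # voxel equal to the global signal
        m = mc.seed_connectivity(_run(small_grid, series), one_voxel_roi,
                                 smoothing_fwhm=0.0)
        assert abs(m.beta_map.data[target]) < 1e-6

    def test_constant_seed_rejected(self, small_grid, one_voxel_roi):
        series = np.ones(small_grid.shape + (30,))
        series[5, 5, 5] = np.arange(30)
        with pytest.raises(ValueError, match="constant seed"):
            mc.seed_connectivity(_run(small_grid, series), one_voxel_roi)

    def test_scale_invariance(self, small_grid, one_voxel_roi):
        rng = np.random.default_rng(5)
        series = rng.standard_normal(small_grid.shape + (40,))
        m1 = mc.seed_connectivity(_run(small_grid, series), one_voxel_roi,
                                  smoothing_fwhm=0.0)
        m2 = mc.seed_connectivity(_run(small_grid, series * 7.5),
                                  one_voxel_roi, smoothing_fwhm=0.0)
        assert np.abs(m1.beta_map.data - m2.beta_map.data).max() < 1e-9


class TestCombineAndGroup:
    def _maps(self, grid, datas):
        return [mc.rsfc.SeedConnectivityMap(
                    "r", f"sub{i}", mc.VolumeMap(grid, d, "correlation"),
                    "subject")
                for i, d in enumerate(datas)]

    def test_identical_runs_unchanged(self, small_grid):
        rng = np.random.default_rng(6)
        d = rng.standard_normal(small_grid.shape)
        out = mc.fixed_effects_combine(self._maps(small_grid, [d, d, d]))
        assert np.allclose(out.beta_map.data, d)

    def test_opposite_maps_cancel(self, small_grid):
        rng = np.random.default_rng(7)
        d = rng.standard_normal(small_grid.shape)
        out = mc.fixed_effects_combine(self._maps(small_grid, [d, -d]))
        assert np.abs(out.beta_map.data).max() < 1e-15

    def test_mean_oracle(self, small_grid):
        rng = np.random.default_rng(8)
        datas = [rng.standard_normal(small_grid.shape) for _ in range(4)]
        out = mc.fixed_effects_combine(self._maps(small_grid, datas))
        assert np.allclose(out.beta_map.data, sum(datas) / 4, atol=1e-12)

    def test_group_mean_and_t_closed_form(self, small_grid):
        rng = np.random.default_rng(9)
        datas = [rng.standard_normal(small_grid.shape) for _ in range(5)]
        g = mc.group_map(self._maps(small_grid, datas), seed=0,
                         n_permutations=32)
        stack = np.stack(datas)
        assert np.allclose(g.beta_map.data, stack.mean(0))
        # textbook one-sample t oracle at an arbitrary voxel
        v = (4, 5, 6)
        x = stack[:, v[0], v[1], v[2]]
        t_expected = x.mean() / (x.std(ddof=1) / np.sqrt(5))
        assert g.t_map.data[v] == pytest.approx(t_expected, rel=1e-12)

    def test_fewer_than_three_subjects_rejected(self, small_grid):
        rng = np.random.default_rng(10)
        datas = [rng.standard_normal(small_grid.shape) for _ in range(2)]
        with pytest.raises(ValueError, match=">= 3"):
            mc.group_map(self._maps(small_grid, datas), seed=0)

    def test_null_subjects_rarely_supra_threshold(self, small_grid):
        # zero-mean noise maps: supra-threshold fraction under max-height
        # sign-flip control stays tiny across replicates
        rng = np.random.default_rng(11)
        total, supra = 0, 0
        for _ in range(20):
            datas = [rng.standard_normal(small_grid.shape) for _ in range(6)]
            g = mc.group_map(self._maps(small_grid, datas), seed=1,
                             n_permutations=64, alpha=0.05)
            supra += int(g.thresholded.sum())
            total += small_grid.n_mask_voxels
        assert supra / total <= 0.001


class TestPlantedTopology:
    def test_block_membership_recovered(self, tiny_world):
        runs = mc.gen_rest_runs(tiny_world, 4, 2, 150, block_rho=0.5,
                                global_amp=0.5)
        vox_net = tiny_world.network_of_voxels()
        margins = []
        for locus, net in zip(tiny_world.loci[:2], tiny_world.networks[:2]):
            roi = mc.sphere_roi(locus, 6.0, tiny_world.grid, roi_id="seed")
            g = mc.GroupConnectivity(runs, roi).fit(seed=5, n_permutations=16)
            vals = g.beta_map.data[tiny_world.grid.mask]
            same = vals[vox_net == net].mean()
            other = vals[vox_net != net].mean()
            margins.append(same - other)
        assert min(margins) >= 0.3
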