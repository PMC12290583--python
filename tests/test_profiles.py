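import numpy as np
import pytest

import metaconn as mc
from metaconn.profiles import (CliqueModel, ProfileMatrix, choose_k,
                               linkage_to_newick, standardized_features)


def _maps(grid, vectors):
    out = {}
    for i, v in enumerate(vectors):
        data = np.zeros(grid.shape)
        data[grid.mask] = v
        out[f"roi{i + 1:02d}"] = mc.VolumeMap(grid, data, "correlation")
    return out


class TestCrossCorr:
    def test_self_correlation_is_one(self, small_grid):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(small_grid.n_mask_voxels)
        pm = mc.crosscorr_matrix(_maps(small_grid, [v, v.copy()]), small_grid)
        assert pm.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self, small_grid):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(small_grid.n_mask_voxels)
        pm = mc.crosscorr_matrix(_maps(small_grid, [v, -v]), small_grid)
        assert pm.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_pearson(self, small_grid):
        rng = np.random.default_rng(2)
        vecs = [rng.standard_normal(small_grid.n_mask_voxels)
                for _ in range(4)]
        pm = mc.crosscorr_matrix(_maps(small_grid, vecs), small_grid)
        for i in range(4):
            for j in range(4):
                a, b = vecs[i], vecs[j]
                am, bm = a - a.mean(), b - b.mean()
                r = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
                assert pm.matrix[i, j] == pytest.approx(r, abs=1e-12)

    def test_constant_map_names_roi(self, small_grid):
        rng = np.random.default_rng(3)
        vecs = [rng.standard_normal(small_grid.n_mask_voxels),
                np.full(small_grid.n_mask_voxels, 3.0)]
        with pytest.raises(ValueError, match="roi02"):
            mc.crosscorr_matrix(_maps(small_grid, vecs), small_grid)


class TestMultimodalAverage:
    def _pm(self, mat, modality):
        return ProfileMatrix(["a", "b", "c"], mat, modality)

    def test_identical_inputs_unchanged(self):
        m = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.1], [0.4, 0.1, 1.0]])
        out = mc.multimodal_average(self._pm(m, "rsfc"), self._pm(m, "macm"))
        assert np.allclose(out.matrix, m)
        assert out.modality == "multimodal"

    def test_elementwise_mean(self):
        a = np.array([[1.0, 0.2, 0.0], [0.2, 1.0, 0.0], [0.0, 0.0, 1.0]])
        b = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.0], [0.0, 0.0, 1.0]])
        out = mc.multimodal_average(self._pm(a, "rsfc"), self._pm(b, "macm"))
        assert out.matrix[0, 1] == pytest.approx(0.4)

    def test_roi_order_mismatch_rejected(self):
        m = np.eye(3)
        a = ProfileMatrix(["a", "b", "c"], m, "rsfc")
        b = ProfileMatrix(["c", "b", "a"], m, "macm")
        with pytest.raises(ValueError, match="order"):
            mc.multimodal_average(a, b)


def _block_profile_matrix(n_blocks=3, per_block=3, within=0.8, between=0.1,
                          jitter=0.0, seed=0):
    """Synthetic profile matrix with planted blocks."""
    M = n_blocks * per_block
    rng = np.random.default_rng(seed)
    mat = np.full((M, M), between)
    for b in range(n_blocks):
        s = slice(b * per_block, (b + 1) * per_block)
        mat[s, s] = within
    if jitter:
        noise = rng.normal(0, jitter, size=(M, M))
        mat += (noise + noise.T) / 2
        np.fill_diagonal(mat, 1.0)
        mat = np.clip(mat, -1, 1)
        # project to PSD (jitter can break it); exact block matrices are
        # already PSD and must stay bit-exact
        w, v = np.linalg.eigh((mat + mat.T) / 2)
        mat = v @ np.diag(np.clip(w, 1e-6, None)) @ v.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
    np.fill_diagonal(mat, 1.0)
    ids = [f"roi{i:02d}" for i in range(M)]
    return ProfileMatrix(ids, mat, "multimodal"), [i // per_block
                                                   for i in range(M)]


class TestClustering:
    def test_duplicate_rows_merge_first_at_height_zero(self):
        # within-block correlation 1.0 makes block rows exact duplicates
        pm, _ = _block_profile_matrix(3, 3, within=1.0)
        Z = mc.hierarchical_cluster(pm)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_merge_heights_monotone(self):
        pm, _ = _block_profile_matrix(3, 3, jitter=0.03, seed=4)
        Z = mc.hierarchical_cluster(pm)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_planted_blocks_recovered_at_k(self):
        pm, truth = _block_profile_matrix(2, 4, jitter=0.02, seed=5)
        res = CliqueModel(pm).fit(override=2)
        labels = [res.assignment[r] for r in pm.roi_ids]
        # same partition up to relabeling
        mapping = {}
        for t, l in zip(truth, labels):
            mapping.setdefault(t, l)
            assert mapping[t] == l

    def test_three_separated_blocks_select_k3(self):
        pm, _ = _block_profile_matrix(3, 3, jitter=0.02, seed=6)
        res = CliqueModel(pm).fit()
        assert res.k == 3

    def test_duplicate_groups_perfect_silhouette_at_k2(self):
        pm, _ = _block_profile_matrix(2, 3, within=1.0)
        Z = mc.hierarchical_cluster(pm)
        k, labels, metrics = choose_k(Z, pm, k_range=[2])
        assert metrics.silhouette.iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_override_honored(self):
        pm, _ = _block_profile_matrix(3, 3, jitter=0.02, seed=7)
        res = CliqueModel(pm).fit(override=4)
        assert len(set(res.assignment.values())) == 4

    def test_order_invariance_up_to_relabeling(self):
        pm, _ = _block_profile_matrix(3, 3, jitter=0.05, seed=8)
        perm = np.random.default_rng(9).permutation(len(pm.roi_ids))
        pm2 = ProfileMatrix([pm.roi_ids[i] for i in perm],
                            pm.matrix[np.ix_(perm, perm)], "multimodal")
        r1 = CliqueModel(pm).fit(override=3)
        r2 = CliqueModel(pm2).fit(override=3)
        # same co-membership relation
        for i, a in enumerate(pm.roi_ids):
            for b in pm.roi_ids[i + 1:]:
                assert ((r1.assignment[a] == r1.assignment[b])
                        == (r2.assignment[a] == r2.assignment[b]))

    def test_zero_variance_column_dropped_with_warning(self):
        # an all-ones matrix is the only unit-diagonal correlation matrix
        # with constant columns: every column must be dropped
        pm = ProfileMatrix(list("abcd"), np.ones((4, 4)), "multimodal")
        with pytest.warns(UserWarning, match="zero-variance"):
            X = standardized_features(pm)
        assert X.shape == (4, 0)


class TestCliqueMeanAndDecode:
    def test_singleton_clique_returns_member_map(self, small_grid):
        rng = np.random.default_rng(10)
        maps = _maps(small_grid, [rng.random(small_grid.n_mask_voxels)])
        out = mc.clique_mean_map(["roi01"], maps)
        assert np.array_equal(out.data, maps["roi01"].data)

    def test_mean_matches_oracle(self, small_grid):
        rng = np.random.default_rng(11)
        vecs = [rng.random(small_grid.n_mask_voxels) for _ in range(3)]
        maps = _maps(small_grid, vecs)
        out = mc.clique_mean_map(list(maps), maps)
        expected = np.mean([m.data for m in maps.values()], axis=0)
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_missing_member_rejected(self, small_grid):
        rng = np.random.default_rng(12)
        maps = _maps(small_grid, [rng.random(small_grid.n_mask_voxels)])
        with pytest.raises(ValueError, match="missing"):
            mc.clique_mean_map(["roi01", "ghost"], maps)

    def test_identical_term_map_ranks_first_with_r_one(self, small_grid):
        rng = np.random.default_rng(13)
        v = rng.standard_normal(small_grid.n_mask_voxels)
        clique = _maps(small_grid, [v])["roi01"]
        terms = {"match": clique,
                 "noise": _maps(small_grid,
                                [rng.standard_normal(len(v))])["roi01"]}
        df = mc.decode_terms(clique, terms)
        assert df.term.iloc[0] == "match"
        assert df.r.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_random_term_excluded_at_threshold(self, small_grid):
        rng = np.random.default_rng(14)
        v = rng.standard_normal(small_grid.n_mask_voxels)
        clique = _maps(small_grid, [v])["roi01"]
        terms = {"noise": _maps(small_grid,
                                [rng.standard_normal(len(v))])["roi01"]}
        df = mc.decode_terms(clique, terms, r_threshold=0.29)
        assert len(df) == 0  # |r| << 0.29 at V >= 1000

    def test_synonym_dedup_keeps_highest_r(self, small_grid):
        rng = np.random.default_rng(15)
        v = rng.standard_normal(small_grid.n_mask_voxels)
        noise = rng.standard_normal(len(v))
        strong = v + 0.5 * noise
        weak = v + 1.2 * noise
        maps = _maps(small_grid, [v, strong, weak])
        clique = maps["roi01"]
        terms = {"working memory": maps["roi02"], "working": maps["roi03"]}
        df = mc.decode_terms(clique, terms,
                             synonym_groups=[["working memory", "working"]])
        assert list(df.term) == ["working memory"]

    def test_empty_term_set_rejected(self, small_grid):
        rng = np.random.default_rng(16)
        clique = _maps(small_grid,
                       [rng.standard_normal(small_grid.n_mask_voxels)])["roi01"]
        with pytest.raises(ValueError, match="empty"):
            mc.decode_terms(clique, {})


def test_newick_export_contains_all_leaves():
    pm, _ = _block_profile_matrix(2, 3, jitter=0.05, seed=17)
    res = CliqueModel(pm).fit(override=2)
    nwk = res.to_newick()
    assert nwk.endswith(";")
    for rid in pm.roi_ids:
        assert rid in nwk
    assert nwk.count("(") == len(pm.roi_ids) - 1
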