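import numpy as np
import pytest

import metaconn as mc
from metaconn.database import CoordinateDatabase


@pytest.fixture(scope="module")
def roi(small_grid):
    return mc.sphere_roi(small_grid.voxel_to_world([9, 9, 8]), 6.0,
                         small_grid, roi_id="seed")


class TestSelectStudies:
    def test_focus_at_center_selected(self, roi):
        db = CoordinateDatabase({"s1": (roi.center_mm.reshape(1, 3), None)})
        assert mc.select_studies(db, roi) == {"s1"}

    def test_focus_just_outside_ball_not_selected(self, roi):
        focus = roi.center_mm + np.array([7.0, 0.0, 0.0])
        db = CoordinateDatabase({"s1": (focus.reshape(1, 3), None)})
        assert mc.select_studies(db, roi) == set()

    def test_matches_brute_force_distance_scan(self, small_grid, roi):
        rng = np.random.default_rng(7)
        db = CoordinateDatabase({
            f"s{i}": (rng.uniform(-28, 28, size=(5, 3)), None)
            for i in range(200)
        })
        got = mc.select_studies(db, roi)
        # all-pairs distance oracle
        expected = set()
        for sid, (foci, _) in db.studies.items():
            for f in foci:
                if np.sqrt(((f - roi.center_mm) ** 2).sum()) <= roi.radius_mm:
                    expected.add(sid)
                    break
        assert got == expected

    def test_monotone_in_radius(self, small_grid):
        rng = np.random.default_rng(8)
        db = CoordinateDatabase({
            f"s{i}": (rng.uniform(-28, 28, size=(5, 3)), None)
            for i in range(100)
        })
        center = small_grid.voxel_to_world([9, 9, 8])
        sels = [mc.select_studies(db, mc.sphere_roi(center, r, small_grid))
                for r in (4.0, 6.0, 10.0)]
        assert sels[0] <= sels[1] <= sels[2]

    def test_empty_database_rejected(self, roi):
        with pytest.raises(ValueError, match="empty"):
            mc.select_studies(CoordinateDatabase({}), roi)


class TestMACM:
    def test_shared_focus_peak_closed_form(self, small_grid, roi):
        # S studies all reporting the same focus: the union of S identical
        # kernels peaks at 1 - (1 - k0)^S
        S = 4
        focus = roi.center_mm.reshape(1, 3)
        db = CoordinateDatabase({f"s{i}": (focus, None) for i in range(S)})
        res = mc.MACM(db, roi, small_grid).fit(threshold=False)
        k0 = mc.build_kernel(15.0, small_grid).peak_value
        expected = 1.0 - (1.0 - k0) ** S
        assert res.unthresholded_map.value_at_mm(roi.center_mm) == \
            pytest.approx(expected, rel=1e-12)

    def test_same_seed_identical_thresholded_map(self, small_grid, roi):
        rng = np.random.default_rng(9)
        db = CoordinateDatabase({
            f"s{i}": (rng.normal(roi.center_mm, 8.0, size=(4, 3)), None)
            for i in range(6)
        })
        r1 = mc.MACM(db, roi, small_grid).fit(n_null_iterations=30, seed=2)
        r2 = mc.MACM(db, roi, small_grid).fit(n_null_iterations=30, seed=2)
        assert np.array_equal(r1.thresholded_map.data, r2.thresholded_map.data)

    def test_zero_selected_studies_degenerate_warning(self, small_grid, roi):
        far = roi.center_mm + np.array([30.0, 0.0, 0.0])
        db = CoordinateDatabase({"s1": (far.reshape(1, 3), None)})
        with pytest.warns(UserWarning, match="degenerate"):
            res = mc.MACM(db, roi, small_grid).fit(threshold=False)
        assert res.degenerate
        assert np.all(res.unthresholded_map.data == 0)

    def test_unthresholded_map_invariant_to_study_order(self, small_grid, roi):
        rng = np.random.default_rng(10)
        foci = {f"s{i}": rng.normal(roi.center_mm, 5.0, size=(3, 3))
                for i in range(5)}
        db1 = CoordinateDatabase({k: (foci[k], None) for k in sorted(foci)})
        db2 = CoordinateDatabase(
            {k: (foci[k], None) for k in sorted(foci, reverse=True)})
        m1 = mc.MACM(db1, roi, small_grid).fit(threshold=False)
        m2 = mc.MACM(db2, roi, small_grid).fit(threshold=False)
        assert np.allclose(m1.unthresholded_map.data,
                           m2.unthresholded_map.data, atol=1e-15)


class TestTermAssociationMaps:
    def test_term_on_all_studies_equals_with_term_ale(self, small_grid):
        rng = np.random.default_rng(11)
        studies = {f"s{i}": (rng.uniform(-20, 20, size=(3, 3)), None)
                   for i in range(4)}
        db = CoordinateDatabase(studies, {s: {"t"} for s in studies})
        with pytest.warns(UserWarning, match="every study"):
            tm = mc.term_association_map(db, "t", small_grid)
        assert tm.data.min() >= 0  # pure with-term ALE, no subtraction

    def test_planted_term_map_peaks_near_locus(self, tiny_world):
        db = mc.gen_coordinate_db(tiny_world, 60, term_signal_fraction=1.0,
                                  scatter_sd_mm=0.0)
        tm = mc.term_association_map(db, "alpha", tiny_world.grid)
        peak_idx = np.unravel_index(np.argmax(tm.data), tm.data.shape)
        peak_mm = tiny_world.grid.voxel_to_world(list(peak_idx))
        net_loci = tiny_world.loci[[i for i, n in
                                    enumerate(tiny_world.networks) if n == 0]]
        d = np.linalg.norm(net_loci - peak_mm, axis=1).min()
        assert d <= 8.0

    def test_disjoint_term_sets_anticorrelated(self, tiny_world):
        db = mc.gen_coordinate_db(tiny_world, 60, term_signal_fraction=1.0,
                                  annotated_fraction=1.0)
        # drop the null term's studies so "alpha" and "beta" partition things
        keep = {s for s, t in db.annotations.items()
                if t & {"alpha", "beta"}}
        db2 = CoordinateDatabase({s: db.studies[s] for s in keep},
                                 {s: db.annotations[s] for s in keep})
        ta = mc.term_association_map(db2, "alpha", tiny_world.grid)
        tb = mc.term_association_map(db2, "beta", tiny_world.grid)
        mask = tiny_world.grid.mask
        r = np.corrcoef(ta.data[mask], tb.data[mask])[0, 1]
        assert r < 0

    def test_unknown_term_rejected(self, small_grid):
        db = CoordinateDatabase({"s1": (np.zeros((1, 3)), None)})
        with pytest.raises(ValueError, match="annotates no studies"):
            mc.term_association_map(db, "missing", small_grid)
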