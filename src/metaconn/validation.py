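"""Planted-ground-truth validation harnesses.

Every routine here exercises the package's own computations on synthetic
study conditions and measures how well the known truth is recovered:
brute-force agreement of the union statistic, Monte-Carlo agreement of the
exact voxel null, false-positive calibration of the cluster-extent FWE
procedure, recovery of planted convergent loci, permutation-subtraction
calibration, coactivation study selection, end-to-end clique recovery and
functional decoding, and the seed-connectivity contract.

All harnesses are pure functions of their seed; sizes default to the
desk-scale study conditions described in the methods note.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .ale import (ALE, ale_cutoff_for_p, ale_null_histogram, ale_union,
                  extract_clusters)
from .database import CoordinateDatabase
from .foci import FociTable
from .grids import VolumeMap, make_grid
from .kernels import build_kernel, kernel_fwhm_from_n, modeled_activation_map
from .macm import MACM, select_studies, term_association_map
from .profiles import (CliqueModel, clique_mean_map, crosscorr_matrix,
                       decode_terms, multimodal_average)
from .rois import rois_from_results, sphere_roi
from .rsfc import GroupConnectivity
from .simulate import SyntheticWorld, gen_coordinate_db, gen_foci_corpus, \
    gen_rest_runs, gen_world_fixture
from .subtraction import ALESubtraction

__all__ = [
    "union_brute_force_error",
    "null_cdf_mc_discrepancy",
    "fwe_false_positive_rate",
    "planted_recovery",
    "subtraction_calibration",
    "macm_selection_check",
    "clique_recovery",
    "decoding_recovery",
    "rsfc_contract",
]


def _calibration_grid():
    """The 4-mm ellipsoid fixture all calibration harnesses run on."""
    return make_grid(4.0, (104.0, 104.0, 88.0),
                     {"type": "ellipsoid", "semi_axes_mm": [48.0, 48.0, 40.0]})


def _fixture_design(n_experiments=15, n_foci=8, n_range=(10, 30)):
    """Fixed corpus design of the calibration fixture: per-experiment
    subject counts evenly spread over the range, 8 foci each.  The design
    (kernel sizes, focus counts) is part of the fixture; only focus
    positions are random, matching the relocation null."""
    ns = np.linspace(n_range[0], n_range[1], n_experiments).round().astype(int)
    return [(n_foci, int(n)) for n in ns]


def _null_corpus_maps(grid, rng, design, kernels=None):
    """MA maps of a fully random (null) corpus: uniform in-mask foci under
    a fixed design."""
    idx = grid.mask_indices
    if kernels is None:
        kernels = [build_kernel(kernel_fwhm_from_n(n), grid)
                   for _, n in design]
    mas = []
    for (n_foci, n_sub), kernel in zip(design, kernels):
        foci = grid.voxel_to_world(idx[rng.integers(0, len(idx), size=n_foci)])
        mas.append(modeled_activation_map(foci, n_sub, grid, kernel=kernel))
    return mas, kernels


# ---------------------------------------------------------------------------
# statistic-level checks
# ---------------------------------------------------------------------------

def union_brute_force_error(seed: int, n_maps: int = 5) -> dict:
    """Max |implementation - brute force| of the probabilistic union on
    random MA maps over a fully masked 10^3 grid."""
    grid = make_grid(4.0, 40.0, "full")
    rng = np.random.default_rng(seed)
    maps = [VolumeMap(grid, rng.uniform(0, 0.5, grid.shape), "MA")
            for _ in range(n_maps)]
    out = ale_union(maps)
    expected = np.ones(grid.shape)
    for m in maps:  # brute-force product loop
        expected *= 1.0 - m.data
    expected = 1.0 - expected
    return {"value": float(np.abs(out.data - expected).max()),
            "n": int(np.prod(grid.shape))}


def null_cdf_mc_discrepancy(seed: int, n_draws: int = 200_000) -> dict:
    """|exact - Monte-Carlo| right-tail probability at the Monte-Carlo 95th
    percentile of the union statistic, on a 2-experiment 100-voxel toy."""
    grid = make_grid(10.0, (40.0, 50.0, 50.0), "full")
    rng = np.random.default_rng(seed)
    maps = [VolumeMap(grid, rng.uniform(0, 0.3, grid.shape), "MA")
            for _ in range(2)]
    null = ale_null_histogram(maps, grid, bin_width=1e-5)
    vals = [m.masked_values for m in maps]
    draws = 1.0 - (1.0 - vals[0][rng.integers(0, len(vals[0]), n_draws)]) * (
        1.0 - vals[1][rng.integers(0, len(vals[1]), n_draws)])
    q95 = np.quantile(draws, 0.95)
    p_exact = float(null.p_of(np.array([q95]))[0])
    p_mc = float((draws >= q95).mean())
    return {"value": abs(p_exact - p_mc), "n": n_draws}


# ---------------------------------------------------------------------------
# FWE calibration and planted recovery
# ---------------------------------------------------------------------------

def fwe_false_positive_rate(seed: int, n_iterations: int = 500,
                            n_replicates: int = 400,
                            n_experiments: int = 15,
                            voxel_p: float = 0.001,
                            n_derivations: int = 4) -> dict:
    """Dataset-level false-positive rate of the cluster-extent FWE chain.

    The full procedure — exact voxel null, voxel-p cutoff, extent threshold
    from ``n_iterations`` Monte-Carlo relocations — is derived
    ``n_derivations`` independent times; after each derivation, freshly
    drawn null corpora (same fixed design, random in-mask foci) are pushed
    through the voxel-null + extent thresholding and the fraction with any
    surviving cluster is recorded.  Averaging over derivations integrates
    over the discreteness of desk-scale cluster sizes, which makes the
    achievable FWE level of a single derivation lumpy; the averaged rate
    estimates the procedure's dataset-level FWE (nominal 0.05).
    """
    grid = _calibration_grid()
    rng = np.random.default_rng(seed)
    design = _fixture_design(n_experiments)
    from .ale import cluster_extent_fwe_threshold
    per = n_replicates // n_derivations
    hits = 0
    total = 0
    for _ in range(n_derivations):
        mas0, kernels = _null_corpus_maps(grid, rng, design)
        null0 = ale_null_histogram(mas0, grid)
        cutoff0 = ale_cutoff_for_p(null0, voxel_p)
        extent, _ = cluster_extent_fwe_threshold(
            [(nf, k) for (nf, _), k in zip(design, kernels)], grid, cutoff0,
            n_iterations=n_iterations, seed=int(rng.integers(2**31)))
        for _ in range(per):
            mas, _ = _null_corpus_maps(grid, rng, design, kernels=kernels)
            null = ale_null_histogram(mas, grid)
            cutoff = ale_cutoff_for_p(null, voxel_p)
            ale = ale_union(mas)
            supra = (ale.data >= cutoff) & grid.mask
            clusters = extract_clusters(supra, grid)
            if len(clusters) and (clusters.n_voxels > extent).any():
                hits += 1
            total += 1
    return {"value": hits / total, "n": total}


_RECOVERY_LOCI = np.array([[-20.0, 16.0, 8.0],
                           [24.0, -12.0, -8.0],
                           [0.0, -16.0, 24.0]])


def planted_recovery(seed: int, n_seeds: int = 20, n_experiments: int = 20,
                     n_noise_foci: int = 5, scatter_sd: float = 5.0,
                     tolerance_mm: float = 8.0,
                     n_iterations: int = 500) -> dict:
    """Fraction of replicates in which the FWE-thresholded map recovers all
    3 planted loci within ``tolerance_mm`` with zero spurious clusters.

    Also reports the largest peak-to-locus error over the successful
    replicates under ``max_peak_error_mm``.
    """
    from scipy import ndimage

    from .ale import STRUCT_26
    grid = _calibration_grid()
    successes = 0
    worst_err = 0.0
    for s in range(n_seeds):
        world = SyntheticWorld(grid=grid, loci=_RECOVERY_LOCI,
                               locus_sd_mm=scatter_sd, networks=[0, 1, 2],
                               term_plan={}, seed=seed * 1000 + s)
        corpus = gen_foci_corpus(world, n_experiments,
                                 n_noise_foci=n_noise_foci)
        res = ALE(corpus.df, grid).fit(n_iterations=n_iterations,
                                       seed=seed * 1000 + s)
        labels, n_clusters = ndimage.label(res.thresholded,
                                           structure=STRUCT_26)
        # a cluster recovers a locus when one of its voxels lies within
        # tolerance of the true center; a cluster near no locus is spurious
        found = np.zeros(len(_RECOVERY_LOCI), dtype=bool)
        spurious = 0
        for c in range(1, n_clusters + 1):
            vox_mm = grid.voxel_to_world(np.argwhere(labels == c))
            d = np.linalg.norm(
                _RECOVERY_LOCI[:, None, :] - vox_mm[None, :, :], axis=2
            ).min(axis=1)
            if d.min() <= tolerance_mm:
                found[d.argmin()] = True
                worst_err = max(worst_err, float(d.min()))
            else:
                spurious += 1
        if found.all() and spurious == 0:
            successes += 1
    return {"value": successes / n_seeds, "n": n_seeds,
            "max_locus_to_cluster_mm": worst_err}


def subtraction_calibration(seed: int, n_replicates: int = 50,
                            n_experiments: int = 12,
                            n_iterations: int = 200) -> dict:
    """Permutation-subtraction null calibration and exactness checks.

    Null-split groups from one random corpus: supra-threshold voxel
    fraction across replicates (should be << 0.001 under max-statistic FWE
    at 0.05 with no extent filter).  Also verifies the a-vs-a zero
    difference and exact antisymmetry on the first replicate, reported as
    0/1 flags.
    """
    grid = _calibration_grid()
    rng = np.random.default_rng(seed)
    supra = 0
    total = 0
    zero_ok = antisym_ok = False
    for r in range(n_replicates):
        world = SyntheticWorld(grid=grid, loci=np.zeros((1, 3)),
                               locus_sd_mm=0.0, networks=[0], term_plan={},
                               seed=int(rng.integers(2**31)))
        corpus = gen_foci_corpus(world, n_experiments, foci_per_locus=0,
                                 n_noise_foci=8,
                                 group_counts={"A": n_experiments // 2,
                                               "B": n_experiments -
                                               n_experiments // 2})
        a, b = corpus.by_group("A"), corpus.by_group("B")
        fit_seed = int(rng.integers(2**31))
        res = ALESubtraction(a, b, grid).fit(n_iterations=n_iterations,
                                             seed=fit_seed, extent_voxels=0)
        supra += int(res.thresholded.sum())
        total += grid.n_mask_voxels
        if r == 0:
            a2 = FociTable(a.df.assign(
                experiment_id=a.df.experiment_id + "_c",
                study_id=a.df.study_id + "_c"))
            zero = ALESubtraction(a, a2, grid).fit(
                n_iterations=100, seed=fit_seed, extent_voxels=0)
            zero_ok = bool(np.abs(zero.diff_map.data).max() == 0.0)
            flipped = ALESubtraction(b, a, grid).fit(
                n_iterations=n_iterations, seed=fit_seed, extent_voxels=0)
            antisym_ok = bool(
                np.array_equal(res.diff_map.data, -flipped.diff_map.data))
    return {"value": supra / total, "n": n_replicates,
            "zero_difference_exact": int(zero_ok),
            "antisymmetry_exact": int(antisym_ok)}


# ---------------------------------------------------------------------------
# coactivation, cliques, decoding, rsFC
# ---------------------------------------------------------------------------

def macm_selection_check(seed: int, n_studies: int = 200) -> dict:
    """Mismatch count between the package's study selection and an
    all-pairs brute-force distance scan; also verifies radius monotonicity
    (violations counted)."""
    grid = _calibration_grid()
    rng = np.random.default_rng(seed)
    db = CoordinateDatabase({
        f"s{i}": (rng.uniform(-40, 40, size=(6, 3)), None)
        for i in range(n_studies)
    })
    center = grid.voxel_to_world([13, 13, 11])
    mismatches = 0
    prev = None
    violations = 0
    for radius in (4.0, 6.0, 10.0):
        roi = sphere_roi(center, radius, grid)
        got = select_studies(db, roi)
        brute = set()
        for sid, (foci, _) in db.studies.items():
            for f in foci:
                if np.sqrt(((f - center) ** 2).sum()) <= radius:
                    brute.add(sid)
                    break
        mismatches += len(got ^ brute)
        if prev is not None and not prev <= got:
            violations += 1
        prev = got
    return {"value": mismatches, "n": n_studies,
            "monotonicity_violations": violations}


def _pipeline_one_seed(seed: int, ale_iterations: int = 300,
                       rest_subjects: int = 6, rest_runs: int = 2,
                       rest_timepoints: int = 120, db_studies: int = 120):
    """Paper-like world -> ALE -> ROIs -> MACM + rsFC -> cliques.

    Returns (world, rois, clique results, macm maps, db)."""
    world = gen_world_fixture("paper-like", seed)
    corpus = gen_foci_corpus(world, 39, n_noise_foci=5,
                             group_counts={"Grammatical": 25,
                                           "Ungrammatical": 14})
    res = ALE(corpus.df, world.grid).fit(n_iterations=ale_iterations,
                                         seed=seed)
    rois = rois_from_results(res)
    if len(rois) < 4:
        return world, rois, None, {}, None
    db = gen_coordinate_db(world, db_studies)
    macm_maps = {r.roi_id: MACM(db, r, world.grid).fit(
        threshold=False).unthresholded_map for r in rois}
    runs = gen_rest_runs(world, rest_subjects, rest_runs, rest_timepoints)
    rsfc_maps = {r.roi_id: GroupConnectivity(runs, r).fit(
        seed=seed, n_permutations=16).beta_map for r in rois}
    pm = multimodal_average(crosscorr_matrix(rsfc_maps, world.grid, "rsfc"),
                            crosscorr_matrix(macm_maps, world.grid, "macm"))
    cliques = CliqueModel(pm).fit()
    return world, rois, cliques, macm_maps, db


def _roi_truth(world, rois):
    out = []
    for r in rois:
        d = np.linalg.norm(world.loci - r.center_mm, axis=1)
        out.append(world.networks[int(d.argmin())])
    return out


def clique_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Fraction of seeds selecting k = 3 and mean adjusted Rand index of
    the recovered cliques against the planted networks."""
    k3 = 0
    aris = []
    for s in range(n_seeds):
        world, rois, cliques, _, _ = _pipeline_one_seed(seed * 100 + s)
        if cliques is None:
            aris.append(0.0)
            continue
        if cliques.k == 3:
            k3 += 1
        truth = _roi_truth(world, rois)
        pred = [cliques.assignment[r.roi_id] for r in rois]
        aris.append(float(adjusted_rand_score(truth, pred)))
    return {"value": float(np.mean(aris)), "n": n_seeds,
            "k3_fraction": k3 / n_seeds}


def decoding_recovery(seed: int) -> dict:
    """Does each planted network's generating term rank first for its
    clique (above the 0.29 threshold), and does the zero-signal term stay
    below it everywhere?

    ``value`` is the fraction of cliques whose top term is the planted one.
    """
    world, rois, cliques, macm_maps, db = _pipeline_one_seed(seed)
    if cliques is None:
        return {"value": 0.0, "n": 0, "null_term_max_r": float("nan"),
                "min_top_r": float("nan")}
    term_maps = {t: term_association_map(db, t, world.grid)
                 for t in db.terms}
    truth = _roi_truth(world, rois)
    net_of_term = {t: n for t, n in world.term_plan.items() if n is not None}
    correct = 0
    total = 0
    null_r = -np.inf
    min_top_r = np.inf
    for c in cliques.cliques:
        members = cliques.members(c)
        nets = [truth[[r.roi_id for r in rois].index(m)] for m in members]
        majority = max(set(nets), key=nets.count)
        cmap = clique_mean_map(members, macm_maps)
        table = decode_terms(cmap, term_maps, r_threshold=-1.0)
        top = table.term.iloc[0]
        total += 1
        if net_of_term.get(top) == majority and table.r.iloc[0] > 0.29:
            correct += 1
            min_top_r = min(min_top_r, float(table.r.iloc[0]))
        nr = table.loc[table.term == "nuisance", "r"]
        if len(nr):
            null_r = max(null_r, float(nr.iloc[0]))
    return {"value": correct / total, "n": total,
            "null_term_max_r": null_r, "min_top_r": min_top_r}


def rsfc_contract(seed: int, rest_timepoints: int = 150) -> dict:
    """Seed-connectivity contract on planted block topology.

    ``value`` is the within-minus-between network connectivity margin of
    group seed maps (>= 0.3 at the preset SNR); the perfect-coupling and
    global-absorption identities are reported as exact flags.
    """
    world = gen_world_fixture("tiny", seed)
    grid = world.grid
    runs = gen_rest_runs(world, 4, 2, rest_timepoints, block_rho=0.5,
                         global_amp=0.5)
    vox_net = world.network_of_voxels()
    margins = []
    for locus, net in zip(world.loci[:2], world.networks[:2]):
        roi = sphere_roi(locus, 6.0, grid, roi_id="seed")
        g = GroupConnectivity(runs, roi).fit(seed=seed, n_permutations=16)
        vals = g.beta_map.data[grid.mask]
        margins.append(float(vals[vox_net == net].mean()
                             - vals[vox_net != net].mean()))

    # perfect-coupling / global-absorption identities on a constructed run
    from .rsfc import RestRun, seed_connectivity
    rng = np.random.default_rng(seed)
    T = 100
    s = rng.standard_normal(T)
    series = np.zeros(grid.shape + (T,))
    roi = sphere_roi(grid.voxel_to_world([8, 8, 7]), 1.0, grid, roi_id="r")
    series[tuple(roi.voxels[0])] = s
    series[4, 4, 4] = s
    series[4, 4, 5] = -2.0 * s  # keeps the global signal at zero
    run = RestRun(grid=grid, series=series, tr_seconds=1.0,
                  subject_id="sub", run_id="run")
    m = seed_connectivity(run, roi, smoothing_fwhm=0.0)
    coupling = float(m.beta_map.data[4, 4, 4])
    return {"value": float(min(margins)), "n": len(runs),
            "perfect_coupling_value": coupling}
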