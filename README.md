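# metaconn

Coordinate-based meta-analysis and connectivity profiling for functional
neuroimaging: activation likelihood estimation (ALE) over reported
activation foci, conjunction and permutation-subtraction contrasts, seed
ROI extraction, meta-analytic coactivation modeling (MACM), seed-based
resting-state functional connectivity (rsFC), multimodal
connectivity-profile correlation, Ward clustering of seed regions into
cliques, and term-based functional decoding — with a synthetic-data module
that plants ground truth for every stage, so the whole chain is testable
on a desk without any external downloads.

It is written for researchers who run coordinate-based meta-analyses (for
example of artificial-grammar / statistical-learning experiments, where
published studies report peak coordinates with Grammatical vs Ungrammatical
contrasts) and want a transparent, fully seeded re-implementation of the
standard analysis chain rather than a black box.

## The statistics at the core

**Modeled activation.** Each reported focus is blurred with an isotropic
Gaussian kernel whose FWHM reflects spatial uncertainty: a between-template
component plus a between-subject component shrinking with `sqrt(n)`
subjects. An experiment's modeled-activation (MA) map takes, per voxel, the
*maximum* over its focus kernels.

**ALE.** The activation likelihood at a voxel is the probabilistic union
over experiments,

```
ALE = 1 - prod_i (1 - MA_i),
```

the probability that at least one experiment's true activation lies there.

**Inference.** Voxel p-values come from an *exact* null distribution,
computed by discretizing each experiment's in-mask MA-value histogram (bin
width 1e-5) and sequentially convolving the histograms under the union
operation — the null of independently random placement of each
experiment's MA values across gray-matter voxels. Cluster-extent
family-wise error is controlled by Monte Carlo: every focus is relocated to
a uniformly drawn in-mask voxel center, the map is rebuilt and thresholded
at p < 0.001, the maximum supra-threshold cluster size (26-connectivity)
is recorded per iteration, and observed clusters must exceed the 95th
percentile of those maxima.

**Contrasts.** Conjunction = minimum-statistic intersection of two
thresholded maps. Subtraction = permutation test on the difference of
unthresholded ALE maps (labels shuffled preserving group sizes), with
max-|difference| FWE control and a contiguity filter.

**Connectivity profiles and cliques.** Pruned ALE peaks (20-mm separation,
strongest first) become 6-mm spherical seeds. Each seed gets a MACM map
(union ALE with a fixed 15-mm kernel over all database studies reporting a
focus in the seed) and a group rsFC map (voxel-wise OLS on the seed mean
time course with a global-signal nuisance regressor, fixed-effects over
runs, one-sample test over subjects). Unthresholded maps are vectorized
and Pearson-correlated into ROI x ROI matrices per modality; their average
is the multimodal matrix. Ward linkage on standardized-Euclidean distances
between its rows groups the seeds into cliques; the cluster count is
chosen by silhouette, with the metric table and dendrogram always exported
for human override. Each clique's mean MACM map is decoded against
term-association maps by spatial correlation, reporting terms with
r > 0.29 after synonym de-duplication.

## Worked example

```python
import metaconn as mc

# a synthetic world with 3 planted networks over 8 convergent loci,
# emulating a 39-experiment corpus (25 Grammatical + 14 Ungrammatical)
world = mc.gen_world_fixture("paper-like", seed=1)
corpus = mc.gen_foci_corpus(world, 39, n_noise_foci=5,
                            group_counts={"Grammatical": 25,
                                          "Ungrammatical": 14})

model = mc.ALE(corpus.df, world.grid)
res = model.fit(voxel_p=0.001, n_iterations=500, seed=42)
print(res.clusters[["cluster", "n_voxels", "volume_mm3", "ale_max",
                    "x", "y", "z"]])
```

prints the FWE-surviving clusters (coordinates in mm):

```
   cluster  n_voxels  volume_mm3   ale_max     x     y     z
0        7        58      3712.0  0.501594  30.0  -6.0 -18.0
1        8        56      3584.0  0.431732  30.0  22.0   6.0
2        1        52      3328.0  0.548348 -38.0  14.0  14.0
3        3        49      3136.0  0.524509 -22.0  34.0 -10.0
4        6        46      2944.0  0.600778  22.0 -34.0  10.0
5        2        45      2880.0  0.487671 -30.0 -26.0 -18.0
6        5        41      2624.0  0.562747   6.0  26.0  26.0
7        4        38      2432.0  0.594298 -10.0 -26.0  26.0
```

— all eight planted loci recovered within one voxel (compare
`world.loci`). Continuing through seeds, coactivation, rest connectivity
and clustering:

```python
from metaconn.rois import rois_from_results
from metaconn.profiles import CliqueModel, crosscorr_matrix, multimodal_average

rois = rois_from_results(res)                    # 8 seed ROIs
db = mc.gen_coordinate_db(world, 120)
macm = {r.roi_id: mc.MACM(db, r, world.grid).fit(threshold=False)
            .unthresholded_map for r in rois}
runs = mc.gen_rest_runs(world, n_subjects=6, n_runs=2, n_timepoints=120)
rsfc = {r.roi_id: mc.GroupConnectivity(runs, r).fit(seed=3)
            .beta_map for r in rois}
pm = multimodal_average(crosscorr_matrix(rsfc, world.grid, "rsfc"),
                        crosscorr_matrix(macm, world.grid, "macm"))
cliques = CliqueModel(pm).fit()
print(cliques.k, cliques.assignment)
```

selects `k = 3` and assigns the 8 seeds to three cliques that match the
planted networks exactly (adjusted Rand index 1.0); decoding each clique's
mean coactivation map ranks its planted generating term first
(r = 0.60–0.67, all above the 0.29 threshold, with the zero-signal
"nuisance" term excluded).

The same chain is available from the shell:

```bash
metaconn run-all --simulate paper-like --outdir run --seed 1
```

writes every stage artifact (NIfTI maps, TSV tables, Newick dendrogram, a
checksum manifest) under `run/` and a human-readable summary under
`run/report/`.

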