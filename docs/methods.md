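# Methods

This note documents the models, numerical choices, and design decisions of
the package, and what its synthetic-data tests do and do not demonstrate
about real data.

## Coordinate-based meta-analysis (ALE)

### Kernels

A reported focus is modeled as an isotropic 3D Gaussian probability
density times the voxel volume, sampled at voxel-center offsets and
truncated where the value falls below `1e-8` of the peak. The FWHM comes
from an empirical spatial-uncertainty model with two components expressed
as mean Euclidean displacements (EUD): a between-template term (5.7 mm)
and a between-subject term (11.6 mm) divided by `sqrt(n)` subjects. EUD
converts to a per-axis sd via `sd = EUD / (2 sqrt(2/pi))`; the two sds add
in quadrature and convert to FWHM. The constants are vendored as JSON data
(`metaconn/data/ale_kernel_constants.json`) and overridable per model —
they are data, not contract. Typical values: FWHM(10) ≈ 10.0 mm,
FWHM(50) ≈ 8.8 mm, strictly decreasing in n.

Foci are snapped to their nearest voxel center before kernel placement
(the kernel is sampled on the voxel lattice), the standard discretization
of coordinate-based meta-analysis tooling. An experiment's MA map is the
voxel-wise **maximum** over its focus kernels; a sum-based variant is
deliberately not offered.

### Union statistic and exact voxel null

`ALE = 1 − Π(1 − MA_i)` per voxel. The voxel-level null assumes each
experiment's MA values independently and uniformly permuted across
in-mask voxels. It is computed exactly: each experiment's in-mask MA
histogram is discretized at bin width `1e-5` (configurable) with values
mapped to bin lower edges, and histograms are convolved sequentially under
the union operation. After each convolution step, bins with probability
mass below `1e-24` are dropped and the pmf renormalised; the discarded
mass is at most `n_experiments × 1e-24 × n_bins ≈ 1e-15`, far below the
`1e-9` pmf-sum tolerance and irrelevant at any p-value of interest. This
pruning is what keeps the exact null fast (sub-second for a 39-experiment
corpus on the test grids) — without it the convolution support grows to
the full bin range.

p-values are the right tail of the discretized null with the observed
value mapped conservatively to its bin's lower edge; `p(0) = 1` exactly.
Observed values above the null support receive the smallest representable
tail mass and a log warning. z is the upper-tail standard-normal quantile
of p, clipped to stay finite.

### Cluster-extent FWE

Per Monte-Carlo iteration, every focus is replaced by a uniformly drawn
in-mask voxel center (per-experiment focus counts and kernels preserved —
the null conditions on the observed corpus design), the ALE map is rebuilt
and thresholded at the fixed ALE cutoff corresponding to the voxel-p
threshold (default 0.001), and the maximum supra-threshold cluster size
under 26-connectivity is recorded. The extent threshold is the ceiling
95th-percentile order statistic of those maxima; observed clusters survive
only if strictly larger. Defaults: 10,000 iterations (tests and the
validation harnesses use 500, a deliberate desk-scale choice; the
threshold estimate enters the calibration results below). Determinism is
complete given (corpus, grid, seed).

At desk scale the max-cluster-size distribution is supported on small
integers, so the achievable FWE level of any single threshold is lumpy
(jumping between roughly 0.025 and 0.08 around the nominal 0.05 depending
on where the order statistic lands among ties). The calibration harness
therefore averages the replicate false-positive rate over several
independent derivations of the full procedure; the averaged rate is the
dataset-level FWE of the procedure as used. At the 2-mm scale of real
analyses cluster sizes are two orders of magnitude larger and the
lumpiness is negligible.

### Conjunction and subtraction

Conjunction is the minimum-statistic intersection: a voxel is retained iff
significant in both thresholded inputs, valued at the smaller ALE. (The
source analysis describes the overlap "common between both" groups; an
actual set union would not produce fewer regions than either input.)

Subtraction: observed contrast = difference of the two groups'
unthresholded ALE maps; null built by shuffling experiment labels
preserving group sizes, 10,000 iterations by default. Per-voxel two-sided
empirical p (floored at `1/(n+1)`), signed z, FWE via the max-|difference|
distribution at 0.05 (Benjamini–Hochberg FDR available as a config
alternative, since both conventions appear in the literature), then a
contiguity filter (100 voxels at full 2-mm scale; configurable, and set to
0 in the desk-scale calibration harness so the max-statistic control is
what is actually exercised). The model canonicalises group order
internally (sorted experiment ids) and flips the output sign if the caller
ordered the groups the other way — this makes
`subtract(A, B) == −subtract(B, A)` hold exactly at the realization level,
not merely in distribution. Groups with fewer than 2 experiments are
refused (degenerate permutation space).

## Seed ROIs

Local maxima: a voxel is a peak iff its value ≥ all 26 neighbors within a
surviving cluster; equal-valued touching candidates form a plateau reduced
to its lexicographically smallest voxel index. Pruning: greedy in
descending value order (ties by voxel index), accepting a peak iff it is
≥ 20 mm from every already-accepted peak, applied **jointly across
clusters** (a per-cluster flag exists). Seeds are closed 6-mm balls of
in-mask voxel centers. Labels come from a user-supplied box table
(nearest/containing region, alphabetical on ties, "unlabeled" outside) —
a configurable stand-in for atlas lookup, which is out of scope.

## Coactivation modeling (MACM)

A database study is selected for a seed iff ≥ 1 of its foci lies in the
closed seed ball (a voxel-set rule is available). The coactivation map is
the union ALE of the selected studies with a fixed 15-mm FWHM kernel
(sample sizes are deliberately not used here). Voxel-level FWE at p <
0.001 uses the max-statistic Monte-Carlo null: all selected studies' foci
relocated uniformly in-mask per iteration, per-iteration maximum ALE
recorded, threshold at the ceiling 99.9th percentile. Downstream profile
correlation always uses the *unthresholded* map, so harnesses that only
need profiles skip the thresholding Monte Carlo. Fewer than 2 selected
studies yields a degenerate (warned) result with the map still produced.

Term-association maps for decoding are built as
`ALE(studies with term) − ALE(studies without term)` with the same 15-mm
kernel — a transparent stand-in for database-derived term maps; externally
supplied maps can be passed anywhere a term map is accepted. If a term
annotates every study the complement is the zero map (logged).

## Resting-state connectivity

Per run: seed and global (whole-mask mean) time courses are extracted from
unsmoothed data; voxel data are smoothed with a 6-mm FWHM Gaussian per
time point; each voxel's series is regressed by OLS on [intercept, seed,
global]; the seed coefficient is standardized to correlation scale
(`beta × sd(seed)/sd(voxel)`) so rsFC and MACM maps are comparable inputs
to the profile correlation (raw betas are one multiplication away).
Constant seeds and seed/global collinearity (|r| > 0.999) are errors.
Subject maps are fixed-effects (unweighted mean) combinations of run maps;
the group map is the voxel-wise mean with a one-sample t across subjects
— a deliberate simplification of the full mixed-effects group model of
large-consortium pipelines. Max-height thresholding uses sign-flip
permutations of subject maps (enumerated when the flip space is small,
sampled otherwise) at the ceiling (1 − α) order statistic of max |t|; a
parametric Bonferroni t cutoff is the config alternative, since published
descriptions of this step mix parametric and nonparametric language.
Smoothing treats out-of-mask voxels as zero, which attenuates values near
the mask edge; at the test grids' mask sizes this is immaterial to the
profile correlations.

## Profiles, cliques, decoding

Unthresholded maps are vectorized over in-mask voxels (V × M) and Pearson
correlated into an M × M matrix per modality; the multimodal matrix is
their element-wise mean and provides the final cluster solution
(per-modality dendrograms are still exported). Clustering features are the
rows of the multimodal matrix, diagonal included; columns are scaled to
unit variance (sd, ddof = 1) — "standardized Euclidean" read as
column-wise scaling, flagged as an open convention; zero-variance columns
are dropped with a warning. Ward minimum-variance linkage on those
Euclidean distances; scipy's deterministic tie-breaking. The cluster count
is `argmax` mean silhouette over k ∈ [2, M−1] (Calinski–Harabasz is also
reported; the silhouette uses exact precomputed distances, since the
quadratic-expansion shortcut adds ~1e-8 noise that breaks the exact
duplicate-row case), with a mandatory export of the metric table and
dendrogram (TSV + Newick) so a human can override k, mirroring the visual
inspection the procedure is meant to automate. Decoding: Pearson spatial
correlation of each clique's mean unthresholded MACM map with every term
map, sorted descending (ties by term name), thresholded at r > 0.29, then
user-supplied synonym groups keep only their highest-r member — synonym
handling is explicitly config-driven, never automatic stemming.

## Synthetic worlds

`gen_world_fixture` provides two presets on 4-mm ellipsoid-masked grids:

- **tiny** — 2 networks / 4 loci (~2,500 in-mask voxels), 12 experiments;
  smoke-test scale.
- **paper-like** — 3 networks / 8 loci (~6,000 voxels), 39 experiments
  split 25/14 between two group labels, echoing the emulated study design
  (the split and the 6–11-maxima layout are configuration echoes, not
  re-derived results). Planted loci are pairwise > 26 mm apart so they
  survive 20-mm pruning as distinct seeds.

Generators: experiments contribute one Gaussian-scattered focus per locus
(sd 5 mm, rejection-truncated to the mask, ≤ 1000 attempts) plus uniform
noise foci; database studies annotated with a term place a fraction
(default 0.7) of their foci near that term's network loci, the rest
uniform, null terms and unannotated studies fully uniform; rest runs
follow `y = global_amp·g(t) + sqrt(ρ)·b_k(t) + noise_sd·ε(t)` with
unit-variance latents, voxel network membership by nearest-locus Voronoi,
and default `noise_sd = sqrt(1−ρ)` so the within-network correlation
equals ρ once the global component is removed. All randomness flows from
one user-visible seed through crc32-keyed child streams, so every
generator is a pure function of (world, parameters, seed) and emitted
files are byte-identical per seed.

What the synthetic world does **not** emulate: anatomically shaped masks,
hemodynamic response and autocorrelated fMRI noise, motion and scanner
artifacts, realistic term co-occurrence structure, publication bias, or
2-mm resolution. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under their stated assumptions — not that
real-data results would be recovered. Real-data peculiarities the chain
must face (non-Gaussian scatter, correlated experiments from shared
samples, heterogeneous reporting) are outside these tests.

A known generator property: Gaussian scatter near the mask boundary is
biased inward by rejection truncation (up to ~2–3 mm for the most
peripheral planted loci at 5-mm scatter on the 4-mm masks). Recovery
tolerances (8 mm) absorb this; the law-of-large-numbers unbiasedness check
uses an interior locus where truncation is immaterial.

## Problem sizes and determinism

The validation harnesses and test suite run on the 4-mm fixtures with
500-iteration Monte-Carlo thresholds, 400 null replicates for FWE
calibration, 20 seeds for planted recovery, 50 replicates for subtraction
calibration, and 10 seeds (6 subjects × 2 runs × 120 time points) for
end-to-end clique recovery — sizes chosen so the full chain exercises
every code path at interactive speed on one CPU. Defaults in
`PipelineConfig` remain at the full-scale values (10,000 iterations).
Every stochastic step takes an explicit seed and fails loudly without one;
pipeline stages derive per-stage child seeds (crc32 of the stage name)
from the single config seed, and re-running a pipeline reproduces all
artifacts checksum-identically.
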