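"""Activation likelihood estimation (ALE) and its inference.

The ALE statistic at a voxel is the probabilistic union of the experiments'
modeled-activation values, ``ALE = 1 - prod_i (1 - MA_i)`` — the probability
that at least one experiment's true activation lies there.  Voxel-level
p-values come from an exact null distribution computed by discretizing each
experiment's in-mask MA-value histogram and sequentially convolving the
histograms under the union operation (the null of independent random
placement of each experiment's MA values across in-mask voxels).  The
cluster-extent family-wise-error threshold comes from a Monte-Carlo null in
which every focus is replaced by a uniformly drawn in-mask voxel center and
the maximum supra-threshold cluster size is recorded per iteration.

The :class:`ALE` model / :class:`ALEResults` pair is the main entry point;
all steps are also exposed as module functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .foci import FociTable
from .grids import BrainGrid, VolumeMap
from .kernels import build_kernel, kernel_fwhm_from_n, modeled_activation_map
from .rois import local_maxima

logger = logging.getLogger(__name__)

__all__ = [
    "ALE",
    "ALEResults",
    "NullModel",
    "ale_union",
    "ale_null_histogram",
    "voxel_pvalues",
    "ale_cutoff_for_p",
    "cluster_extent_fwe_threshold",
    "extract_clusters",
    "conjunction",
]

#: 26-connectivity structuring element for cluster labeling
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
DEFAULT_BIN_WIDTH = 1e-5
#: probability-mass floor below which null histogram bins are dropped
#: (renormalised afterwards; discarded mass is ~1e-15, see methods note)
PMF_PRUNE = 1e-24


# ---------------------------------------------------------------------------
# union statistic
# ---------------------------------------------------------------------------

def ale_union(ma_maps: list) -> VolumeMap:
    """ALE map: per-voxel probabilistic union of MA maps."""
    if len(ma_maps) == 0:
        raise ValueError("need at least one MA map")
    grid = ma_maps[0].grid
    acc = np.ones(grid.shape)
    for m in ma_maps:
        grid.check_same(m.grid)
        acc *= 1.0 - m.data
    return VolumeMap(grid, 1.0 - acc, "ALE")


# ---------------------------------------------------------------------------
# exact voxel-level null (histogram convolution)
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Discretized null distribution of the ALE statistic.

    ``null_pmf[k]`` is the probability mass of the bin with lower edge
    ``k * bin_width``; the Monte-Carlo records (max cluster size and max
    statistic per iteration) are filled by the FWE routines.
    """

    bin_width: float
    null_pmf: np.ndarray
    mc_max_cluster_sizes: list = field(default_factory=list)
    mc_max_stats: list = field(default_factory=list)
    n_iterations: int = 0

    def __post_init__(self):
        s = float(self.null_pmf.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"null pmf must sum to 1 (got {s})")

    @property
    def survival(self) -> np.ndarray:
        """sf[k] = P(binned null ALE >= k * bin_width)."""
        if not hasattr(self, "_sf"):
            self._sf = np.cumsum(self.null_pmf[::-1])[::-1]
        return self._sf

    def p_of(self, values: np.ndarray) -> np.ndarray:
        """Right-tail p-values, observed values mapped to their bin's lower
        edge (conservative).  Values above the null support get the smallest
        representable tail mass (logged)."""
        v = np.asarray(values, dtype=float)
        k = np.floor(v / self.bin_width + 1e-9).astype(np.int64)
        sf = self.survival
        over = k >= len(sf)
        if over.any():
            logger.warning(
                "%d observed ALE value(s) above null support; assigned the "
                "smallest representable tail mass", int(over.sum()),
            )
        k = np.clip(k, 0, len(sf) - 1)
        p = np.clip(sf[k], None, 1.0)
        p[k == 0] = 1.0  # P(null >= 0) is exactly 1
        floor = sf[sf > 0].min()
        p = np.maximum(p, floor)
        if over.any():
            p[over] = floor
        return p


def _ma_bin_hist(values: np.ndarray, bin_width: float, n_bins: int) -> np.ndarray:
    idx = np.floor(values / bin_width + 1e-9).astype(np.int64)
    return np.bincount(idx, minlength=n_bins).astype(float) / len(values)


def ale_null_histogram(
    ma_maps: list,
    grid: BrainGrid,
    bin_width: float = DEFAULT_BIN_WIDTH,
    prune: float = PMF_PRUNE,
) -> NullModel:
    """Exact null of the union statistic by sequential histogram convolution.

    Each experiment's in-mask MA values are histogrammed at ``bin_width``;
    the union null is built by convolving histograms pairwise under
    ``u = 1 - (1-a)(1-b)``, binning scores to lower edges.  Bins with mass
    below ``prune`` are dropped and the pmf renormalised (error ~1e-15).
    """
    if len(ma_maps) == 0:
        raise ValueError("need at least one MA map")
    if grid.n_mask_voxels == 0:
        raise ValueError("empty mask")
    max_ale = 1.0
    prod = 1.0
    for m in ma_maps:
        prod *= 1.0 - float(m.masked_values.max())
    max_ale = 1.0 - prod
    n_bins = int(np.floor(max_ale / bin_width + 1e-9)) + 2

    pmf = _ma_bin_hist(ma_maps[0].masked_values, bin_width, n_bins)
    edges = np.arange(n_bins) * bin_width
    for m in ma_maps[1:]:
        h = _ma_bin_hist(m.masked_values, bin_width, n_bins)
        ia = np.flatnonzero(pmf)
        ib = np.flatnonzero(h)
        score = 1.0 - np.outer(1.0 - edges[ia], 1.0 - edges[ib])
        k = np.floor(score / bin_width + 1e-9).astype(np.int64).ravel()
        w = np.outer(pmf[ia], h[ib]).ravel()
        pmf = np.bincount(k, weights=w, minlength=n_bins)
        if prune > 0:
            pmf[pmf < prune] = 0.0
        pmf /= pmf.sum()
    return NullModel(bin_width=bin_width, null_pmf=pmf)


def voxel_pvalues(ale_map: VolumeMap, null_model: NullModel):
    """p and z maps from the discretized null CDF.

    p is the right tail ``P(null >= observed)`` with the observed value
    mapped conservatively to its bin's lower edge; z is the upper-tail
    standard-normal quantile of p.
    """
    grid = ale_map.grid
    p = np.ones(grid.shape)
    p[grid.mask] = null_model.p_of(ale_map.data[grid.mask])
    z = np.zeros(grid.shape)
    with np.errstate(divide="ignore"):
        # clip keeps z finite (p = 1 would map to -inf)
        z[grid.mask] = norm.isf(np.clip(p[grid.mask], 1e-300, 1.0 - 1e-16))
    return VolumeMap(grid, p, "p"), VolumeMap(grid, z, "z")


def ale_cutoff_for_p(null_model: NullModel, voxel_p: float) -> float:
    """Smallest ALE value whose right-tail p falls below ``voxel_p``.

    A voxel is supra-threshold iff its ALE value >= this cutoff (consistent
    with the lower-edge binning of :meth:`NullModel.p_of`).
    """
    sf = null_model.survival
    below = np.flatnonzero(sf < voxel_p)
    if len(below) == 0:
        return np.inf
    return float(below[0] * null_model.bin_width)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def extract_clusters(
    thresholded: np.ndarray, grid: BrainGrid, ale_map: VolumeMap | None = None
) -> pd.DataFrame:
    """Connected components (26-connectivity) of a thresholded map.

    Returns one row per cluster: ``cluster, n_voxels, volume_mm3, ale_max,
    x, y, z`` (peak mm; ties broken by smallest flat index) and, when the
    statistic map is given, the cluster's sub-maxima (list of (x, y, z,
    value), sorted descending).  An empty map yields an empty table.
    """
    mask3d = np.asarray(thresholded, dtype=bool) & grid.mask
    labels, n = ndimage.label(mask3d, structure=STRUCT_26)
    rows = []
    vol = grid.voxel_volume_mm3
    values = ale_map.data if ale_map is not None else mask3d.astype(float)
    for c in range(1, n + 1):
        where = labels == c
        idx = np.argwhere(where)
        vals = values[where]
        best = int(np.argmax(vals))  # argmax over argwhere order = smallest flat idx
        peak_idx = idx[best]
        peak_mm = grid.voxel_to_world(peak_idx)
        row = {
            "cluster": c,
            "n_voxels": int(where.sum()),
            "volume_mm3": float(where.sum() * vol),
            "ale_max": float(vals[best]),
            "x": float(peak_mm[0]),
            "y": float(peak_mm[1]),
            "z": float(peak_mm[2]),
        }
        if ale_map is not None:
            peaks = local_maxima(ale_map, labels == c)
            row["sub_maxima"] = [
                (float(p.x), float(p.y), float(p.z), float(p.value)) for p in peaks
            ]
        rows.append(row)
    cols = ["cluster", "n_voxels", "volume_mm3", "ale_max", "x", "y", "z"]
    if ale_map is not None:
        cols.append("sub_maxima")
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("volume_mm3", ascending=False, kind="stable").reset_index(
        drop=True
    ) if len(df) else df


def _max_cluster_size(supra: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=STRUCT_26)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _ceiling_percentile(samples: np.ndarray, q: float) -> float:
    """Conservative (ceiling) order statistic at quantile q in (0, 1)."""
    s = np.sort(np.asarray(samples))
    k = int(np.ceil(q * len(s)))
    k = min(max(k, 1), len(s))
    return float(s[k - 1])


def cluster_extent_fwe_threshold(
    experiments: list,
    grid: BrainGrid,
    ale_cutoff: float,
    n_iterations: int = 10000,
    seed: int | None = None,
    fwe: float = 0.05,
    kernels: dict | None = None,
) -> tuple[int, list]:
    """Monte-Carlo cluster-extent threshold at family-wise error ``fwe``.

    ``experiments`` is a list of ``(n_foci, kernel)`` pairs; per iteration
    every focus is relocated to a uniformly drawn in-mask voxel center
    (per-experiment focus counts and kernels preserved), the ALE map is
    recomputed and thresholded at ``ale_cutoff`` (the voxel-level p
    threshold mapped through the null CDF), and the maximum supra-threshold
    cluster size (26-connectivity) is recorded.  The returned threshold is
    the ceiling 95th-percentile order statistic; observed clusters must be
    strictly LARGER than it to survive.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    mask_idx = grid.mask_indices
    n_mask = len(mask_idx)
    maxima = []
    for _ in range(n_iterations):
        acc = np.ones(grid.shape)
        for n_foci, kernel in experiments:
            hw = kernel.halfwidth
            padded = np.zeros(tuple(s + 2 * h for s, h in zip(grid.shape, hw)))
            draws = mask_idx[rng.integers(0, n_mask, size=n_foci)]
            for row in draws:
                sl = tuple(
                    slice(row[a], row[a] + 2 * hw[a] + 1) for a in range(3)
                )
                np.maximum(padded[sl], kernel.cube, out=padded[sl])
            ma = padded[hw[0] : hw[0] + grid.shape[0],
                        hw[1] : hw[1] + grid.shape[1],
                        hw[2] : hw[2] + grid.shape[2]]
            acc *= 1.0 - ma
        ale = 1.0 - acc
        supra = (ale >= ale_cutoff) & grid.mask
        maxima.append(_max_cluster_size(supra))
    threshold = int(_ceiling_percentile(np.asarray(maxima), 1.0 - fwe))
    return threshold, maxima


def conjunction(
    thresholded_a: np.ndarray,
    thresholded_b: np.ndarray,
    ale_a: VolumeMap,
    ale_b: VolumeMap,
) -> VolumeMap:
    """Minimum-statistic conjunction: voxels significant in BOTH inputs,
    valued at the minimum of the two ALE statistics."""
    ale_a.grid.check_same(ale_b.grid)
    both = np.asarray(thresholded_a, bool) & np.asarray(thresholded_b, bool)
    out = np.where(both, np.minimum(ale_a.data, ale_b.data), 0.0)
    return VolumeMap(ale_a.grid, out, "ALE")


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ALE:
    """ALE meta-analysis model over a foci table on a grid.

    Parameters
    ----------
    foci : FociTable or pandas.DataFrame
        Activation peaks; Talairach rows are converted on construction.
    grid : BrainGrid
        Analysis grid with in-brain mask.
    bin_width : float
        Discretization step of the exact voxel-level null.
    kernel_constants : dict, optional
        Override for the sample-size -> FWHM uncertainty constants.
    """

    def __init__(self, foci, grid: BrainGrid, bin_width: float = DEFAULT_BIN_WIDTH,
                 kernel_constants: dict | None = None):
        if isinstance(foci, pd.DataFrame):
            foci = FociTable(foci)
        self.foci = foci.to_mni()
        self.grid = grid
        self.bin_width = bin_width
        self.kernel_constants = kernel_constants
        self._ma_maps = None
        self._kernels = {}

    def _kernel_for_n(self, n: int):
        if n not in self._kernels:
            fwhm = kernel_fwhm_from_n(n, constants=self.kernel_constants)
            self._kernels[n] = build_kernel(fwhm, self.grid)
        return self._kernels[n]

    @property
    def experiments(self) -> list:
        """(experiment_id, group, n_subjects, foci_mm) tuples."""
        return list(self.foci.experiments())

    def ma_maps(self) -> list:
        """Per-experiment modeled activation maps (cached)."""
        if self._ma_maps is None:
            self._ma_maps = [
                modeled_activation_map(f, n, self.grid, kernel=self._kernel_for_n(n))
                for (_, _, n, f) in self.experiments
            ]
        return self._ma_maps

    def fit(
        self,
        voxel_p: float = 0.001,
        n_iterations: int = 10000,
        seed: int | None = None,
        fwe: float = 0.05,
    ) -> "ALEResults":
        """Run the full inference chain: MA -> ALE -> exact null -> p/z ->
        Monte-Carlo cluster-extent FWE -> cluster table."""
        mas = self.ma_maps()
        ale_map = ale_union(mas)
        null = ale_null_histogram(mas, self.grid, bin_width=self.bin_width)
        p_map, z_map = voxel_pvalues(ale_map, null)
        cutoff = ale_cutoff_for_p(null, voxel_p)
        extent, maxima = cluster_extent_fwe_threshold(
            [(len(f), self._kernel_for_n(n)) for (_, _, n, f) in self.experiments],
            self.grid, cutoff, n_iterations=n_iterations, seed=seed, fwe=fwe,
        )
        null.mc_max_cluster_sizes = list(maxima)
        null.n_iterations = n_iterations
        supra = (ale_map.data >= cutoff) & self.grid.mask
        labels, n = ndimage.label(supra, structure=STRUCT_26)
        keep = np.zeros_like(supra)
        for c in range(1, n + 1):
            where = labels == c
            if where.sum() > extent:
                keep |= where
        clusters = extract_clusters(keep, self.grid, ale_map)
        return ALEResults(
            model=self,
            ale_map=ale_map,
            p_map=p_map,
            z_map=z_map,
            null_model=null,
            voxel_threshold_p=voxel_p,
            ale_cutoff=cutoff,
            extent_threshold_voxels=extent,
            thresholded=keep,
            clusters=clusters,
            seed=seed,
        )


@dataclass
class ALEResults:
    """Fitted ALE meta-analysis: maps, thresholds and the cluster table."""

    model: ALE
    ale_map: VolumeMap
    p_map: VolumeMap
    z_map: VolumeMap
    null_model: NullModel
    voxel_threshold_p: float
    ale_cutoff: float
    extent_threshold_voxels: int
    thresholded: np.ndarray
    clusters: pd.DataFrame
    seed: int | None

    @property
    def thresholded_map(self) -> VolumeMap:
        return VolumeMap(
            self.ale_map.grid,
            np.where(self.thresholded, self.ale_map.data, 0.0),
            "ALE",
        )

    def summary(self, labeler=None) -> pd.DataFrame:
        """Cluster table in the conventional layout: one row per cluster
        peak plus indented rows per sub-maximum (cluster, x, y, z,
        volume_mm3, ale_max, label)."""
        rows = []
        for _, c in self.clusters.iterrows():
            subs = c.get("sub_maxima", []) or []
            first = True
            listed = subs if subs else [(c.x, c.y, c.z, c.ale_max)]
            for (x, y, z, v) in listed:
                rows.append({
                    "cluster": int(c.cluster) if first else "",
                    "x": x, "y": y, "z": z,
                    "volume_mm3": c.volume_mm3 if first else np.nan,
                    "ale_max": v,
                    "label": labeler((x, y, z)) if labeler else "unlabeled",
                })
                first = False
        return pd.DataFrame(
            rows, columns=["cluster", "x", "y", "z", "volume_mm3", "ale_max", "label"]
        )
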