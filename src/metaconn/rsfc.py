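"""Seed-based resting-state functional connectivity (desk scale).

Mirrors the standard seed-based pipeline contract: extract the seed's mean
time course and the global (whole-mask mean) signal, smooth the voxel data,
regress each voxel's series on [intercept, seed, global] by ordinary least
squares, carry the seed coefficient standardized to a correlation-scale
value, combine runs within subject by a fixed-effects (unweighted mean)
average, and form the group map with a one-sample test across subjects
thresholded by sign-flip permutation of the maximum height.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.stats import t as t_dist

from .grids import BrainGrid, VolumeMap
from .rois import SeedROI

__all__ = [
    "RestRun",
    "seed_timecourse",
    "global_timecourse",
    "seed_connectivity",
    "fixed_effects_combine",
    "group_map",
    "SeedConnectivityMap",
    "GroupConnectivity",
]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class RestRun:
    """One resting-state acquisition: (x, y, z, t) series on a grid."""

    grid: BrainGrid
    series: np.ndarray
    tr_seconds: float
    subject_id: str
    run_id: str

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.series.shape[:3] != self.grid.shape:
            raise ValueError("series spatial shape does not match grid")
        if self.series.shape[3] < 20:
            raise ValueError("a rest run needs >= 20 time points")
        if not np.all(np.isfinite(self.series[self.grid.mask])):
            raise ValueError("non-finite values in rest series")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[3]


@dataclass
class SeedConnectivityMap:
    """Correlation-scale seed coefficient map at run/subject/group level."""

    roi_id: str
    subject_id: str
    beta_map: VolumeMap
    level: str  # run | subject | group
    n_subjects: int | None = None
    t_map: VolumeMap | None = None
    threshold: float | None = None
    thresholded: np.ndarray | None = None


def seed_timecourse(run: RestRun, roi: SeedROI) -> np.ndarray:
    """Unweighted mean over ROI voxels per time point."""
    in_mask = run.grid.mask[tuple(roi.voxels.T)]
    vox = roi.voxels[in_mask]
    if len(vox) == 0:
        raise ValueError(f"ROI {roi.roi_id} has no voxels inside the run mask")
    return run.series[tuple(vox.T)].mean(axis=0)


def global_timecourse(run: RestRun) -> np.ndarray:
    """Whole-mask mean series (the global-signal nuisance regressor)."""
    return run.series[run.grid.mask].mean(axis=0)


def _smooth_series(run: RestRun, fwhm_mm: float) -> np.ndarray:
    if fwhm_mm <= 0:
        return run.series
    sigma_vox = (fwhm_mm / _FWHM_FACTOR) / run.grid.voxel_size
    out = np.empty_like(run.series)
    for t in range(run.n_timepoints):
        out[..., t] = ndimage.gaussian_filter(run.series[..., t], sigma=sigma_vox)
    return out


def seed_connectivity(run: RestRun, roi: SeedROI,
                      smoothing_fwhm: float = 6.0) -> SeedConnectivityMap:
    """Run-level seed map: OLS of each (smoothed) voxel series on
    [intercept, seed, global]; the seed coefficient is standardized to the
    correlation scale (beta * sd(seed) / sd(voxel)).

    Raises on a constant seed series or seed/global collinearity
    (|r| > 0.999).
    """
    seed = seed_timecourse(run, roi)
    glob = global_timecourse(run)
    if np.std(seed) == 0:
        raise ValueError("constant seed series")
    if np.std(glob) > 0:
        r_sg = np.corrcoef(seed, glob)[0, 1]
        if abs(r_sg) > 0.999:
            raise ValueError(
                f"seed and global regressors are collinear (|r|={abs(r_sg):.4f})"
            )
    data = _smooth_series(run, smoothing_fwhm)
    Y = data[run.grid.mask].T  # (T, V)
    T = Y.shape[0]
    X = np.column_stack([np.ones(T), seed, glob])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    sd_vox = Y.std(axis=0, ddof=1)
    sd_seed = seed.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(sd_vox > 0, beta[1] * sd_seed / sd_vox, 0.0)
    vol = np.zeros(run.grid.shape)
    vol[run.grid.mask] = value
    return SeedConnectivityMap(
        roi_id=roi.roi_id, subject_id=run.subject_id,
        beta_map=VolumeMap(run.grid, vol, "correlation"), level="run",
    )


def fixed_effects_combine(run_maps: list) -> SeedConnectivityMap:
    """Subject-level map: voxel-wise unweighted mean across run maps."""
    if len(run_maps) == 0:
        raise ValueError("need >= 1 run map")
    grid = run_maps[0].beta_map.grid
    for m in run_maps[1:]:
        grid.check_same(m.beta_map.grid)
    mean = np.mean([m.beta_map.data for m in run_maps], axis=0)
    return SeedConnectivityMap(
        roi_id=run_maps[0].roi_id, subject_id=run_maps[0].subject_id,
        beta_map=VolumeMap(grid, mean, "correlation"), level="subject",
    )


def _signflip_max_t(stack: np.ndarray, mask: np.ndarray, n_permutations: int,
                    rng) -> np.ndarray:
    """Max-|t| distribution over sign flips of subject maps (enumerated when
    the flip space is small enough, sampled otherwise)."""
    n_sub = stack.shape[0]
    vals = stack[:, mask]
    if 2 ** n_sub <= n_permutations:
        signs_iter = (np.array(s) for s in product((1.0, -1.0), repeat=n_sub))
        n_total = 2 ** n_sub
    else:
        signs_iter = (rng.choice([1.0, -1.0], size=n_sub)
                      for _ in range(n_permutations))
        n_total = n_permutations
    out = np.empty(n_total)
    for i, s in enumerate(signs_iter):
        flipped = vals * s[:, None]
        m = flipped.mean(axis=0)
        sd = flipped.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, m / (sd / np.sqrt(n_sub)), 0.0)
        out[i] = np.abs(t).max()
    return out


def group_map(subject_maps: list, alpha: float = 0.001,
              n_permutations: int = 1024, seed: int | None = None,
              method: str = "signflip") -> SeedConnectivityMap:
    """Group-level map: voxel-wise mean and one-sample t across subjects,
    with maximum-height thresholding.

    ``method="signflip"`` (default) thresholds |t| at the ceiling
    (1−alpha) order statistic of the sign-flip max-|t| distribution;
    ``method="parametric"`` uses the Bonferroni-corrected t quantile.
    Requires >= 3 subjects.
    """
    if len(subject_maps) < 3:
        raise ValueError("group analysis requires >= 3 subjects")
    grid = subject_maps[0].beta_map.grid
    for m in subject_maps[1:]:
        grid.check_same(m.beta_map.grid)
    stack = np.stack([m.beta_map.data for m in subject_maps])
    n_sub = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n_sub)), 0.0)

    if method == "signflip":
        rng = np.random.default_rng(seed)
        max_t = _signflip_max_t(stack, grid.mask, n_permutations, rng)
        s = np.sort(max_t)
        k = min(max(int(np.ceil((1.0 - alpha) * len(s))), 1), len(s))
        thr = float(s[k - 1])
    elif method == "parametric":
        thr = float(t_dist.isf(alpha / (2 * grid.n_mask_voxels), df=n_sub - 1))
    else:
        raise ValueError(f"unknown thresholding method {method!r}")

    supra = (np.abs(t) > thr) & grid.mask
    return SeedConnectivityMap(
        roi_id=subject_maps[0].roi_id, subject_id="group",
        beta_map=VolumeMap(grid, mean, "correlation"), level="group",
        n_subjects=n_sub, t_map=VolumeMap(grid, t, "tstat"),
        threshold=thr, thresholded=supra,
    )


class GroupConnectivity:
    """Convenience model: runs -> subject maps -> group map for one seed."""

    def __init__(self, runs: list, roi: SeedROI, smoothing_fwhm: float = 6.0):
        self.runs = runs
        self.roi = roi
        self.smoothing_fwhm = smoothing_fwhm

    def fit(self, alpha: float = 0.001, n_permutations: int = 1024,
            seed: int | None = None, method: str = "signflip") -> SeedConnectivityMap:
        by_subject: dict = {}
        for run in self.runs:
            by_subject.setdefault(run.subject_id, []).append(run)
        subject_maps = []
        for sid in sorted(by_subject):
            run_maps = [seed_connectivity(r, self.roi, self.smoothing_fwhm)
                        for r in by_subject[sid]]
            subject_maps.append(fixed_effects_combine(run_maps))
        return group_map(subject_maps, alpha=alpha,
                         n_permutations=n_permutations, seed=seed, method=method)
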