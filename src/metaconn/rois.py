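"""Seed ROIs: local maxima, separation pruning, spheres, labeling.

Thresholded meta-analytic clusters are turned into seed regions: every
26-neighborhood local maximum of the statistic map inside a cluster is a
candidate peak; peaks closer than a minimum separation (20 mm by default)
to a stronger already-accepted peak are pruned; each surviving peak gets a
6-mm-radius spherical ROI of in-mask voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import BrainGrid, VolumeMap

logger = logging.getLogger(__name__)

__all__ = ["Peak", "SeedROI", "local_maxima", "prune_peaks", "sphere_roi", "label_roi"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class Peak:
    """A local maximum of a statistic map (mm coordinate + value)."""

    x: float
    y: float
    z: float
    value: float
    cluster_id: int = 0
    voxel: tuple = (0, 0, 0)

    @property
    def mm(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class SeedROI:
    """A spherical seed region on the grid.

    ``voxels`` is the (N, 3) array of in-mask voxel indices whose centers
    lie within ``radius_mm`` of ``center_mm`` (closed ball).
    """

    roi_id: str
    center_mm: np.ndarray
    radius_mm: float
    voxels: np.ndarray
    value: float = np.nan
    label: str = "unlabeled"

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.size == 0:
            raise ValueError(f"ROI {self.roi_id} has an empty voxel set")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def mask_array(self, grid: BrainGrid) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m

    def contains_mm(self, coords_mm) -> np.ndarray:
        """Closed-ball membership test for world-mm points."""
        coords = np.atleast_2d(np.asarray(coords_mm, float))
        d = np.linalg.norm(coords - self.center_mm, axis=1)
        return d <= self.radius_mm + 1e-12


def local_maxima(stat_map: VolumeMap, cluster_mask: np.ndarray) -> list:
    """Local maxima of a statistic map within a cluster mask.

    A voxel is a local maximum iff its value is >= all 26 neighbors and it
    lies in the cluster.  A flat plateau of equal-valued touching maxima
    yields one peak at the lexicographically smallest voxel index.  Output
    sorted descending by value (ties by smallest index).
    """
    cm = np.asarray(cluster_mask, dtype=bool)
    if not cm.any():
        return []
    grid = stat_map.grid
    v = np.where(cm, stat_map.data, -np.inf)
    neigh_max = ndimage.maximum_filter(v, footprint=_STRUCT_26, mode="constant",
                                       cval=-np.inf)
    cand = cm & (stat_map.data > 0) & (v >= neigh_max)
    if not cand.any():
        return []
    # touching candidates necessarily share the same value -> plateau
    labels, n = ndimage.label(cand, structure=_STRUCT_26)
    peaks = []
    for c in range(1, n + 1):
        idx = np.argwhere(labels == c)  # argwhere is lexicographic
        vox = tuple(int(a) for a in idx[0])
        mm = grid.voxel_to_world(idx[0])
        peaks.append(Peak(x=float(mm[0]), y=float(mm[1]), z=float(mm[2]),
                          value=float(stat_map.data[vox]), voxel=vox))
    peaks.sort(key=lambda p: (-p.value, p.voxel))
    return peaks


def prune_peaks(peaks: list, min_separation_mm: float = 20.0) -> list:
    """Greedy separation pruning, strongest first.

    Peaks are visited in descending value order (ties by smallest voxel
    index); a peak is accepted iff its Euclidean distance to every
    already-accepted peak is >= ``min_separation_mm``.  Deterministic; the
    accepted set is pairwise separated by construction.
    """
    ordered = sorted(peaks, key=lambda p: (-p.value, p.voxel))
    accepted: list = []
    for p in ordered:
        if all(np.linalg.norm(p.mm - q.mm) >= min_separation_mm for q in accepted):
            accepted.append(p)
    return accepted


def sphere_roi(center_mm, radius_mm: float, grid: BrainGrid,
               roi_id: str = "roi", value: float = np.nan) -> SeedROI:
    """Spherical ROI: in-mask voxels whose centers lie within the closed
    ball of ``radius_mm`` around ``center_mm``."""
    center = np.asarray(center_mm, dtype=float)
    coords = grid.mask_coords_mm
    idx = grid.mask_indices
    inside = np.linalg.norm(coords - center, axis=1) <= radius_mm + 1e-12
    if not inside.any():
        raise ValueError(
            f"sphere at {center.tolist()} (r={radius_mm} mm) contains no "
            "in-mask voxel centers"
        )
    return SeedROI(roi_id=roi_id, center_mm=center, radius_mm=float(radius_mm),
                   voxels=idx[inside], value=value)


def label_roi(center_mm, label_table) -> str:
    """Look up a text label for a coordinate from a region table.

    ``label_table`` is a list of ``(name, min_mm, max_mm)`` axis-aligned
    boxes.  The label of the first containing box (alphabetically first on
    ties, logged) is returned, or ``"unlabeled"`` when no box contains the
    point.
    """
    c = np.asarray(center_mm, dtype=float)
    hits = []
    for name, lo, hi in label_table:
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        if np.all(c >= lo) and np.all(c <= hi):
            hits.append(str(name))
    if not hits:
        return "unlabeled"
    hits.sort()
    if len(hits) > 1:
        logger.info("label tie at %s between %s; using %s", c.tolist(), hits, hits[0])
    return hits[0]


def rois_from_results(results, radius_mm: float = 6.0,
                      min_separation_mm: float = 20.0,
                      per_cluster: bool = False,
                      label_table=None) -> list:
    """Full ROI chain from fitted ALE results: per-cluster local maxima,
    joint (or per-cluster) separation pruning, spheres.

    Returns a list of :class:`SeedROI` ordered by descending peak value.
    """
    grid = results.ale_map.grid
    labels, n = ndimage.label(results.thresholded, structure=_STRUCT_26)
    all_peaks = []
    for c in range(1, n + 1):
        for p in local_maxima(results.ale_map, labels == c):
            all_peaks.append(Peak(p.x, p.y, p.z, p.value, cluster_id=c,
                                  voxel=p.voxel))
    if per_cluster:
        pruned = []
        for c in range(1, n + 1):
            pruned.extend(prune_peaks([p for p in all_peaks if p.cluster_id == c],
                                      min_separation_mm))
        pruned.sort(key=lambda p: (-p.value, p.voxel))
    else:
        pruned = prune_peaks(all_peaks, min_separation_mm)
    rois = []
    for i, p in enumerate(pruned):
        roi = sphere_roi(p.mm, radius_mm, grid, roi_id=f"roi{i + 1:02d}",
                         value=p.value)
        if label_table is not None:
            roi.label = label_roi(p.mm, label_table)
        rois.append(roi)
    return rois


def roi_table(rois: list) -> pd.DataFrame:
    return pd.DataFrame(
        [{"roi_id": r.roi_id, "x": r.center_mm[0], "y": r.center_mm[1],
          "z": r.center_mm[2], "value": r.value, "label": r.label,
          "n_voxels": r.n_voxels} for r in rois]
    )
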