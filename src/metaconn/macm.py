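"""Meta-analytic connectivity modeling (MACM) and term-association maps.

MACM asks which brain regions coactivate with a seed across the task
literature: all database studies reporting at least one focus inside the
seed sphere are selected, their foci are modeled with a FIXED 15-mm FWHM
kernel (not sample-size dependent), and the probabilistic-union ALE of the
selected studies is the seed's coactivation map.  Voxel-level FWE uses the
max-statistic Monte-Carlo null (random in-mask relocation of all selected
studies' foci).  Downstream profile correlation uses the UNTHRESHOLDED map.

Term-association maps — the decoding reference — are built as the
difference of the with-term and without-term ALE maps (a transparent
stand-in for database-derived term maps; externally supplied maps can be
dropped in wherever a term map is accepted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .database import CoordinateDatabase
from .grids import BrainGrid, VolumeMap
from .kernels import build_kernel, modeled_activation_map
from .rois import SeedROI

__all__ = ["select_studies", "MACM", "MACMResult", "term_association_map"]

MACM_FWHM_MM = 15.0


def select_studies(db: CoordinateDatabase, roi: SeedROI,
                   rule: str = "sphere", grid: BrainGrid | None = None) -> set:
    """Studies reporting >= 1 focus inside the seed.

    ``rule="sphere"`` (default) tests the closed ball around the ROI center
    at the ROI radius; ``rule="voxels"`` tests membership of the focus's
    nearest voxel in the ROI voxel set (requires ``grid``).
    """
    if len(db) == 0:
        raise ValueError("empty coordinate database")
    selected = set()
    if rule == "sphere":
        for sid, (foci, _) in db.studies.items():
            if roi.contains_mm(foci).any():
                selected.add(sid)
    elif rule == "voxels":
        if grid is None:
            raise ValueError("rule='voxels' requires the grid")
        vox_set = {tuple(v) for v in roi.voxels}
        for sid, (foci, _) in db.studies.items():
            idx = np.atleast_2d(grid.world_to_voxel(foci, strict=False))
            if any(tuple(v) in vox_set for v in idx):
                selected.add(sid)
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return selected


def _union_ale(foci_sets: list, grid: BrainGrid, kernel) -> VolumeMap:
    acc = np.ones(grid.shape)
    for foci in foci_sets:
        ma = modeled_activation_map(foci, None, grid, kernel=kernel)
        acc *= 1.0 - ma.data
    return VolumeMap(grid, 1.0 - acc, "ALE")


class MACM:
    """Coactivation model of one seed ROI against a coordinate database."""

    def __init__(self, db: CoordinateDatabase, roi: SeedROI, grid: BrainGrid,
                 fwhm_mm: float = MACM_FWHM_MM, selection_rule: str = "sphere"):
        self.db = db
        self.roi = roi
        self.grid = grid
        self.fwhm_mm = fwhm_mm
        self.kernel = build_kernel(fwhm_mm, grid)
        self.selected = select_studies(db, roi, rule=selection_rule, grid=grid)

    def fit(self, n_null_iterations: int = 10000, seed: int | None = None,
            fwe_p: float = 0.001, threshold: bool = True) -> "MACMResult":
        """Coactivation ALE of the selected studies with optional
        voxel-level max-statistic FWE thresholding at ``fwe_p``."""
        sel = sorted(self.selected)
        degenerate = len(sel) < 2
        if degenerate:
            warnings.warn(
                f"ROI {self.roi.roi_id}: only {len(sel)} selected studies; "
                "MACM result is degenerate", stacklevel=2,
            )
        if len(sel) == 0:
            zero = VolumeMap(self.grid, np.zeros(self.grid.shape), "ALE")
            return MACMResult(self.roi.roi_id, [], zero, None, fwe_p,
                              np.nan, True, seed)
        foci_sets = [self.db.foci_of(s) for s in sel]
        unthresh = _union_ale(foci_sets, self.grid, self.kernel)
        thresh_map = None
        crit = np.nan
        if threshold and not degenerate:
            if seed is None:
                raise ValueError("a seed is required for the Monte-Carlo null")
            rng = np.random.default_rng(seed)
            mask_idx = self.grid.mask_indices
            counts = [len(f) for f in foci_sets]
            max_stats = np.empty(n_null_iterations)
            for it in range(n_null_iterations):
                rand_sets = [
                    self.grid.voxel_to_world(
                        mask_idx[rng.integers(0, len(mask_idx), size=c)]
                    )
                    for c in counts
                ]
                null_ale = _union_ale(rand_sets, self.grid, self.kernel)
                max_stats[it] = null_ale.masked_values.max()
            crit = float(np.quantile(max_stats, 1.0 - fwe_p, method="higher"))
            thresh_map = VolumeMap(
                self.grid,
                np.where(unthresh.data > crit, unthresh.data, 0.0),
                "ALE",
            )
        return MACMResult(self.roi.roi_id, sel, unthresh, thresh_map, fwe_p,
                          crit, degenerate, seed)


@dataclass
class MACMResult:
    roi_id: str
    selected_study_ids: list
    unthresholded_map: VolumeMap
    thresholded_map: VolumeMap | None
    voxel_fwe_p: float
    critical_value: float
    degenerate: bool
    seed: int | None


def term_association_map(db: CoordinateDatabase, term, grid: BrainGrid,
                         fwhm_mm: float = MACM_FWHM_MM) -> VolumeMap:
    """Association map of a term: ALE(studies WITH term) − ALE(studies
    WITHOUT term), both with the fixed coactivation kernel.

    When every study carries the term the complement is the zero map (the
    with-term ALE is returned unchanged).
    """
    withs = db.studies_with_term(term)
    if not withs:
        raise ValueError(f"term {term!r} annotates no studies")
    withouts = [s for s in db.study_ids if s not in set(withs)]
    kernel = build_kernel(fwhm_mm, grid)
    with_map = _union_ale([db.foci_of(s) for s in withs], grid, kernel)
    if not withouts:
        warnings.warn(
            f"term {term!r} annotates every study; complement taken as zero",
            stacklevel=2,
        )
        without = np.zeros(grid.shape)
    else:
        without = _union_ale([db.foci_of(s) for s in withouts], grid, kernel).data
    return VolumeMap(grid, with_map.data - without, "other")
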