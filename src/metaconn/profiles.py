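"""Connectivity-profile matrices, clique clustering, and functional decoding.

Each seed ROI's unthresholded connectivity maps (task-independent rsFC and
task-dependent coactivation) are vectorized over the in-mask voxels and
Pearson-correlated pairwise, giving one M x M profile matrix per modality;
their element-wise mean is the multimodal matrix that provides the final
cluster solution.  ROIs are agglomerated with Ward's minimum-variance
linkage on standardized-Euclidean distances between profile rows; the
cluster count is chosen by silhouette (with the per-k metric table and
dendrogram always exported so a human can override).  Each clique's mean
unthresholded coactivation map is decoded against term-association maps by
spatial correlation, reporting terms above r = 0.29 after synonym
de-duplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .grids import BrainGrid, VolumeMap

__all__ = [
    "ProfileMatrix",
    "crosscorr_matrix",
    "multimodal_average",
    "standardized_features",
    "hierarchical_cluster",
    "choose_k",
    "CliqueModel",
    "CliqueResults",
    "clique_mean_map",
    "decode_terms",
    "linkage_to_newick",
]

DECODE_R_THRESHOLD = 0.29


@dataclass
class ProfileMatrix:
    """M x M Pearson correlation matrix of connectivity profiles."""

    roi_ids: list
    matrix: np.ndarray
    modality: str  # rsfc | macm | multimodal

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        M = len(self.roi_ids)
        if m.shape != (M, M):
            raise ValueError("matrix shape does not match roi_ids")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("profile matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise ValueError("profile matrix must have unit diagonal")
        if m.min() < -1 - 1e-9 or m.max() > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh((m + m.T) / 2).min() < -1e-8:
            raise ValueError("profile matrix is not PSD within tolerance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.roi_ids, columns=self.roi_ids)


def crosscorr_matrix(maps: dict, grid: BrainGrid,
                     modality: str = "other") -> ProfileMatrix:
    """Pearson-correlate all pairs of in-mask-vectorized maps.

    ``maps`` is an ordered mapping roi_id -> VolumeMap; a constant map is
    an error naming the ROI.
    """
    roi_ids = list(maps)
    if len(roi_ids) < 2:
        raise ValueError("need >= 2 maps")
    vecs = []
    for rid in roi_ids:
        m = maps[rid]
        grid.check_same(m.grid)
        v = m.data[grid.mask]
        if np.std(v) == 0:
            raise ValueError(f"map for ROI {rid!r} is constant in-mask")
        vecs.append(v)
    corr = np.corrcoef(np.stack(vecs))
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ProfileMatrix(roi_ids=roi_ids, matrix=corr, modality=modality)


def multimodal_average(matrix_rsfc: ProfileMatrix,
                       matrix_macm: ProfileMatrix) -> ProfileMatrix:
    """Element-wise mean of the two modality matrices (same ROI order)."""
    if matrix_rsfc.roi_ids != matrix_macm.roi_ids:
        raise ValueError("ROI ids/order differ between modality matrices")
    avg = (matrix_rsfc.matrix + matrix_macm.matrix) / 2.0
    np.fill_diagonal(avg, 1.0)
    return ProfileMatrix(roi_ids=list(matrix_rsfc.roi_ids), matrix=avg,
                         modality="multimodal")


def standardized_features(pm: ProfileMatrix) -> np.ndarray:
    """Profile rows with columns scaled to unit variance (sd ddof=1);
    zero-variance columns are dropped with a warning."""
    X = pm.matrix.copy()
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance profile column(s)",
            stacklevel=2,
        )
    X = X[:, keep] / sd[keep]
    return X


def hierarchical_cluster(pm: ProfileMatrix) -> np.ndarray:
    """Ward minimum-variance linkage on standardized-Euclidean distances
    between profile rows.  Returns the scipy linkage matrix (deterministic;
    scipy breaks distance ties on the smallest cluster-index pair)."""
    if len(pm.roi_ids) < 3:
        raise ValueError("need >= 3 ROIs to cluster")
    X = standardized_features(pm)
    d = pdist(X, metric="euclidean")
    return linkage(d, method="ward")


def choose_k(Z: np.ndarray, pm: ProfileMatrix, k_range=None,
             override: int | None = None):
    """Cluster-count selection by mean silhouette (Calinski–Harabasz also
    reported); ``override`` forces k regardless of the metrics.

    Returns ``(k, assignment_labels, metrics_df)`` where metrics_df has one
    row per candidate k.
    """
    M = len(pm.roi_ids)
    if k_range is None:
        k_range = range(2, M)
    k_range = [k for k in k_range]
    if not k_range:
        raise ValueError("empty k_range")
    if any(k < 2 or k > M - 1 for k in k_range):
        raise ValueError(f"k_range must lie within [2, {M - 1}]")
    X = standardized_features(pm)
    # exact pairwise distances (sklearn's quadratic-expansion shortcut adds
    # ~1e-8 noise that breaks the duplicate-row silhouette == 1 case)
    D = squareform(pdist(X, metric="euclidean"))
    rows = []
    labels_by_k = {}
    for k in k_range:
        lab = fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        if len(np.unique(lab)) < 2:
            sil, ch = np.nan, np.nan
        else:
            sil = float(silhouette_score(D, lab, metric="precomputed"))
            ch = float(calinski_harabasz_score(X, lab))
        rows.append({"k": k, "silhouette": sil, "calinski_harabasz": ch})
    metrics = pd.DataFrame(rows)
    if override is not None:
        k_best = int(override)
        if k_best not in labels_by_k:
            labels_by_k[k_best] = fcluster(Z, t=k_best, criterion="maxclust")
    else:
        valid = metrics.dropna(subset=["silhouette"])
        k_best = int(valid.sort_values(["silhouette", "k"],
                                       ascending=[False, True]).iloc[0]["k"])
    return k_best, labels_by_k[k_best], metrics


class CliqueModel:
    """Clique clustering model over a (multimodal) profile matrix."""

    def __init__(self, profile_matrix: ProfileMatrix):
        self.pm = profile_matrix

    def fit(self, k_range=None, override: int | None = None) -> "CliqueResults":
        Z = hierarchical_cluster(self.pm)
        k, labels, metrics = choose_k(Z, self.pm, k_range=k_range,
                                      override=override)
        assignment = dict(zip(self.pm.roi_ids, (int(v) for v in labels)))
        return CliqueResults(model=self, linkage=Z, k=k, assignment=assignment,
                             selection_metrics=metrics)


@dataclass
class CliqueResults:
    """A clique solution: linkage tree, chosen k, ROI -> clique assignment."""

    model: CliqueModel
    linkage: np.ndarray
    k: int
    assignment: dict
    selection_metrics: pd.DataFrame

    def members(self, clique: int) -> list:
        return [r for r, c in self.assignment.items() if c == clique]

    @property
    def cliques(self) -> list:
        return sorted(set(self.assignment.values()))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"roi_id": r, "clique": c} for r, c in self.assignment.items()]
        )

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage, self.model.pm.roi_ids)


def clique_mean_map(members: list, unthresholded_maps: dict) -> VolumeMap:
    """Voxel-wise mean of the member ROIs' unthresholded coactivation maps."""
    missing = [m for m in members if m not in unthresholded_maps]
    if missing:
        raise ValueError(f"missing member map(s): {missing}")
    if not members:
        raise ValueError("empty clique")
    maps = [unthresholded_maps[m] for m in members]
    grid = maps[0].grid
    for m in maps[1:]:
        grid.check_same(m.grid)
    return VolumeMap(grid, np.mean([m.data for m in maps], axis=0), "other")


def decode_terms(clique_map: VolumeMap, term_maps: dict,
                 r_threshold: float = DECODE_R_THRESHOLD,
                 synonym_groups: list | None = None) -> pd.DataFrame:
    """Rank terms by spatial correlation with the clique map.

    Pearson correlation over in-mask voxels against every term map, sorted
    descending (ties by term name); terms with r > ``r_threshold`` are
    kept; within each synonym group only the highest-r term is reported.
    """
    if not term_maps:
        raise ValueError("empty term map set")
    grid = clique_map.grid
    v = clique_map.data[grid.mask]
    rows = []
    for term, tm in term_maps.items():
        grid.check_same(tm.grid)
        u = tm.data[grid.mask]
        if np.std(u) == 0 or np.std(v) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(v, u)[0, 1])
        rows.append({"term": term, "r": r})
    df = pd.DataFrame(rows).sort_values(["r", "term"], ascending=[False, True])
    df = df[df["r"] > r_threshold].reset_index(drop=True)
    if synonym_groups:
        drop = set()
        for group in synonym_groups:
            in_table = df[df["term"].isin(set(group))]
            if len(in_table) > 1:
                drop |= set(in_table["term"].iloc[1:])  # keep the top-r one
        df = df[~df["term"].isin(drop)].reset_index(drop=True)
    return df


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Render a scipy linkage matrix as a Newick tree (branch lengths from
    merge heights)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: str(labels[i]) for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        node = n + i
        nodes[node] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[node] = h
    return nodes[n + len(Z) - 1] + ";"
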