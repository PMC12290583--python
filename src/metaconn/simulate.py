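"""Synthetic worlds with planted ground truth.

Everything the pipeline consumes can be generated here: a foci corpus with
K convergent loci (Gaussian spatial scatter) plus uniform noise foci, a
term-annotated coordinate database whose annotated studies concentrate
foci near their term's network, and block-covariance rest runs with a
global-signal component.  All generators are pure functions of
(world, parameters, seed) via a splittable RNG, so every stage can be
re-run independently and emitted files are byte-identical per seed.

Presets:

``tiny``
    2 networks / 4 loci on a small ellipsoid grid, 12 experiments —
    end-to-end smoke-test scale.
``paper-like``
    3 networks / 8 loci, 39 experiments split 25 "Grammatical" +
    14 "Ungrammatical" — echoing the published study design (the split and
    layout are configuration echoes, not re-derived results).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .database import CoordinateDatabase
from .foci import FociTable
from .grids import BrainGrid, make_grid
from .rsfc import RestRun

__all__ = [
    "SyntheticWorld",
    "gen_world_fixture",
    "gen_foci_corpus",
    "gen_coordinate_db",
    "gen_rest_runs",
    "PRESETS",
]


@dataclass
class SyntheticWorld:
    """Ground truth of a synthetic study: grid, planted loci, network
    partition, term plan, and the master seed."""

    grid: BrainGrid
    loci: np.ndarray               # (K, 3) mm centers
    locus_sd_mm: float             # Gaussian scatter of convergent foci
    networks: list                 # per-locus network id (ints)
    term_plan: dict                # term -> network id, or None for a null term
    seed: int

    def __post_init__(self):
        self.loci = np.atleast_2d(np.asarray(self.loci, dtype=float))
        idx = self.grid.world_to_voxel(self.loci)
        in_mask = self.grid.mask[tuple(np.atleast_2d(idx).T)]
        if not np.all(in_mask):
            raise ValueError("planted locus outside the mask")
        if len(self.networks) != len(self.loci):
            raise ValueError("networks must partition the loci")

    @property
    def n_networks(self) -> int:
        return len(set(self.networks))

    def rng(self, *stream) -> np.random.Generator:
        """Child RNG for a named stream, split from the master seed.

        Stream names are hashed with crc32 (stable across processes, unlike
        the built-in ``hash``) so every generator is a pure function of
        (world, parameters, seed)."""
        key = [self.seed] + [zlib.crc32(repr(s).encode()) for s in stream]
        return np.random.default_rng(np.random.SeedSequence(key))

    def network_of_voxels(self) -> np.ndarray:
        """Network id per in-mask voxel: that of the nearest locus (Voronoi)."""
        coords = self.grid.mask_coords_mm
        d = np.linalg.norm(coords[:, None, :] - self.loci[None, :, :], axis=2)
        return np.asarray(self.networks)[np.argmin(d, axis=1)]

    def ground_truth(self) -> dict:
        return {
            "seed": self.seed,
            "loci_mm": self.loci.tolist(),
            "locus_sd_mm": self.locus_sd_mm,
            "networks": list(map(int, self.networks)),
            "term_plan": {t: (int(n) if n is not None else None)
                          for t, n in self.term_plan.items()},
        }


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _paper_like(seed: int) -> SyntheticWorld:
    grid = make_grid(4.0, (104.0, 104.0, 88.0),
                     {"type": "ellipsoid", "semi_axes_mm": [48.0, 48.0, 40.0]})
    loci = np.array([
        [-36.0, 16.0, 12.0],   # network 0
        [-24.0, 36.0, -12.0],  # network 0
        [32.0, 22.0, 4.0],     # network 0
        [4.0, 28.0, 30.0],     # network 1
        [30.0, -8.0, -20.0],   # network 1
        [-8.0, -30.0, 28.0],   # network 2
        [24.0, -34.0, 12.0],   # network 2
        [-30.0, -28.0, -16.0], # network 2
    ])
    networks = [0, 0, 0, 1, 1, 2, 2, 2]
    term_plan = {"language": 0, "salience": 1, "control": 2, "nuisance": None}
    return SyntheticWorld(grid=grid, loci=loci, locus_sd_mm=5.0,
                          networks=networks, term_plan=term_plan, seed=seed)


def _tiny(seed: int) -> SyntheticWorld:
    grid = make_grid(4.0, (72.0, 72.0, 64.0),
                     {"type": "ellipsoid", "semi_axes_mm": [32.0, 32.0, 28.0]})
    loci = np.array([
        [-18.0, 14.0, 8.0],
        [16.0, 18.0, -6.0],
        [-12.0, -18.0, 12.0],
        [14.0, -16.0, -10.0],
    ])
    networks = [0, 0, 1, 1]
    term_plan = {"alpha": 0, "beta": 1, "nuisance": None}
    return SyntheticWorld(grid=grid, loci=loci, locus_sd_mm=5.0,
                          networks=networks, term_plan=term_plan, seed=seed)


PRESETS = {"tiny": _tiny, "paper-like": _paper_like}

#: grid definition per preset (voxel size, extent, ellipsoid semi-axes, mm)
PRESET_GRID_SPEC = {
    "tiny": {"voxel_size_mm": 4.0, "extent_mm": (72.0, 72.0, 64.0),
             "mask_semi_axes_mm": (32.0, 32.0, 28.0)},
    "paper-like": {"voxel_size_mm": 4.0, "extent_mm": (104.0, 104.0, 88.0),
                   "mask_semi_axes_mm": (48.0, 48.0, 40.0)},
}

#: study-design constants of the emulated corpus (config echoes)
GROUP_COUNTS = {"paper-like": {"Grammatical": 25, "Ungrammatical": 14},
                "tiny": {"Grammatical": 8, "Ungrammatical": 4}}


def gen_world_fixture(preset_name: str, seed: int) -> SyntheticWorld:
    """Deterministic world per (preset, seed)."""
    if preset_name not in PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[preset_name](seed)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _truncated_gaussian(rng, center, sd, grid: BrainGrid,
                        max_attempts: int = 1000) -> np.ndarray:
    """Isotropic Gaussian draw rejected until its nearest voxel center is
    in-mask."""
    for _ in range(max_attempts):
        pt = rng.normal(loc=center, scale=sd, size=3) if sd > 0 else np.array(
            center, float)
        idx = grid.world_to_voxel(pt, strict=False)
        if grid.mask[tuple(idx)]:
            return pt
    raise RuntimeError(
        f"could not draw an in-mask point near {center} after {max_attempts} "
        "attempts"
    )


def _uniform_mask_points(rng, grid: BrainGrid, n: int) -> np.ndarray:
    idx = grid.mask_indices
    return grid.voxel_to_world(idx[rng.integers(0, len(idx), size=n)])


def gen_foci_corpus(world: SyntheticWorld, n_experiments: int,
                    foci_per_locus: int = 1, n_noise_foci: int = 5,
                    n_subjects_range=(10, 30),
                    group_counts: dict | None = None,
                    sd_mm: float | None = None) -> FociTable:
    """Synthetic meta-analysis corpus.

    Per experiment: ``foci_per_locus`` foci per planted locus drawn from an
    isotropic Gaussian (``sd_mm``, default the world's scatter) truncated
    to the mask, plus ``n_noise_foci`` uniform in-mask foci; n_subjects
    uniform in range; group labels assigned in blocks per ``group_counts``.
    """
    if n_experiments < 1 or foci_per_locus < 0 or n_noise_foci < 0:
        raise ValueError("corpus parameters must be positive")
    sd = world.locus_sd_mm if sd_mm is None else sd_mm
    rng = world.rng("foci", n_experiments)
    if group_counts is None:
        group_counts = {"Grammatical": n_experiments}
    if sum(group_counts.values()) != n_experiments:
        raise ValueError("group_counts must sum to n_experiments")
    labels = [g for g, c in group_counts.items() for _ in range(c)]

    rows = []
    for e in range(n_experiments):
        exp_id = f"exp{e + 1:03d}"
        n_sub = int(rng.integers(n_subjects_range[0], n_subjects_range[1] + 1))
        foci = []
        for locus in world.loci:
            for _ in range(foci_per_locus):
                foci.append(_truncated_gaussian(rng, locus, sd, world.grid))
        if n_noise_foci:
            foci.extend(_uniform_mask_points(rng, world.grid, n_noise_foci))
        for xyz in foci:
            rows.append({
                "study_id": f"study{e + 1:03d}", "experiment_id": exp_id,
                "group": labels[e], "n": n_sub, "space": "MNI",
                "x": round(float(xyz[0]), 3), "y": round(float(xyz[1]), 3),
                "z": round(float(xyz[2]), 3),
            })
    return FociTable(pd.DataFrame(rows))


def gen_coordinate_db(world: SyntheticWorld, n_studies: int,
                      term_signal_fraction: float = 0.7,
                      foci_per_study: int = 8,
                      scatter_sd_mm: float = 6.0,
                      annotated_fraction: float = 0.75) -> CoordinateDatabase:
    """Synthetic term-annotated coordinate database.

    Annotated studies are allocated round-robin across the world's term
    plan; a study carrying a term places ``term_signal_fraction`` of its
    foci near that term's network loci (Gaussian scatter), the rest
    uniform.  Null-plan terms (network None) and unannotated studies place
    all foci uniformly.
    """
    for term, net in world.term_plan.items():
        if net is not None and net not in set(world.networks):
            raise ValueError(f"term {term!r} references unknown network {net}")
    rng = world.rng("db", n_studies)
    terms = list(world.term_plan)
    n_annotated = int(round(annotated_fraction * n_studies))
    studies: dict = {}
    annotations: dict = {}
    net_loci = {n: world.loci[[i for i, m in enumerate(world.networks) if m == n]]
                for n in set(world.networks)}
    for s in range(n_studies):
        sid = f"db{s + 1:04d}"
        term = terms[s % len(terms)] if s < n_annotated else None
        net = world.term_plan.get(term) if term else None
        n_signal = (int(round(term_signal_fraction * foci_per_study))
                    if net is not None else 0)
        foci = []
        for _ in range(n_signal):
            locus = net_loci[net][rng.integers(0, len(net_loci[net]))]
            foci.append(_truncated_gaussian(rng, locus, scatter_sd_mm, world.grid))
        remaining = foci_per_study - n_signal
        if remaining:
            foci.extend(_uniform_mask_points(rng, world.grid, remaining))
        studies[sid] = (np.asarray(foci), int(rng.integers(10, 31)))
        if term is not None:
            annotations[sid] = {term}
    return CoordinateDatabase(studies=studies, annotations=annotations)


def gen_rest_runs(world: SyntheticWorld, n_subjects: int, n_runs: int,
                  n_timepoints: int, block_rho: float = 0.5,
                  global_amp: float = 0.5,
                  noise_sd: float | None = None,
                  tr_seconds: float = 1.0) -> list:
    """Block-covariance rest runs.

    Per time point, a voxel's value is ``global_amp * g(t) +
    sqrt(block_rho) * b_k(t) + noise_sd * e(t)`` where ``g`` is the shared
    global signal, ``b_k`` the unit-variance latent of the voxel's network
    (nearest-locus Voronoi assignment), and ``e`` white noise.  With the
    default ``noise_sd = sqrt(1 - block_rho)`` the within-network
    correlation equals ``block_rho`` in expectation once the global
    component is removed.
    """
    if not (0 <= block_rho < 1):
        raise ValueError("block_rho must lie in [0, 1)")
    if n_timepoints < 50:
        raise ValueError("n_timepoints must be >= 50")
    if noise_sd is None:
        noise_sd = float(np.sqrt(1.0 - block_rho))
    grid = world.grid
    vox_net = world.network_of_voxels()
    net_ids = sorted(set(world.networks))
    runs = []
    for s in range(n_subjects):
        for r in range(n_runs):
            rng = world.rng("rest", s, r)
            g = rng.standard_normal(n_timepoints)
            b = {n: rng.standard_normal(n_timepoints) for n in net_ids}
            V = grid.n_mask_voxels
            noise = rng.standard_normal((V, n_timepoints))
            block = np.stack([b[n] for n in vox_net])  # (V, T)
            sig = (global_amp * g[None, :]
                   + np.sqrt(block_rho) * block
                   + noise_sd * noise)
            series = np.zeros(grid.shape + (n_timepoints,))
            series[grid.mask] = sig
            runs.append(RestRun(grid=grid, series=series,
                                tr_seconds=tr_seconds,
                                subject_id=f"sub{s + 1:02d}",
                                run_id=f"run{r + 1}"))
    return runs
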