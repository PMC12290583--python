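"""End-to-end pipeline: simulate/load -> ALE -> contrasts -> ROIs -> MACM +
rsFC -> profile matrices -> clique clustering -> decoding.

A :class:`PipelineConfig` (YAML-serializable) carries every threshold,
kernel setting, iteration count and the master seed; :func:`run_pipeline`
executes the stages in order, writing every intermediate artifact, a
machine-readable manifest (input checksums, seed, package version) and a
summary report.  Stages are resumable: a stage whose ``.done`` marker
exists is skipped and its artifacts re-loaded, so deleting one stage's
outputs and re-running reproduces them from upstream artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ale import ALE, conjunction
from .database import load_database, save_database
from .foci import FociTable, load_foci_table
from .grids import BrainGrid, VolumeMap, make_grid, read_volume, write_volume
from .macm import MACM, term_association_map
from .profiles import (CliqueModel, ProfileMatrix, clique_mean_map,
                       crosscorr_matrix, decode_terms, multimodal_average)
from .rois import rois_from_results, roi_table, sphere_roi
from .rsfc import GroupConnectivity, RestRun
from .simulate import GROUP_COUNTS, PRESET_GRID_SPEC, gen_coordinate_db, \
    gen_foci_corpus, gen_rest_runs, gen_world_fixture
from .subtraction import ALESubtraction

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ale", "contrast", "rois", "macm", "rsfc", "profile",
          "cluster", "decode")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips through YAML unchanged."""

    # paths (inputs; filled by the simulate stage when simulating)
    foci_path: str | None = None
    db_foci_path: str | None = None
    db_annotations_path: str | None = None
    rest_manifest_path: str | None = None
    output_dir: str = "run"
    # grid
    voxel_size_mm: float = 4.0
    extent_mm: tuple = (104.0, 104.0, 88.0)
    mask_semi_axes_mm: tuple = (48.0, 48.0, 40.0)
    # thresholds
    voxel_p: float = 0.001
    fwe: float = 0.05
    subtraction_extent_voxels: int = 100
    macm_fwe_p: float = 0.001
    decode_r: float = 0.29
    rsfc_alpha: float = 0.001
    # iterations
    ale_iterations: int = 10000
    subtraction_iterations: int = 10000
    macm_iterations: int = 10000
    rsfc_permutations: int = 1024
    # kernels / rois
    bin_width: float = 1e-5
    macm_fwhm_mm: float = 15.0
    rsfc_smoothing_fwhm_mm: float = 6.0
    roi_radius_mm: float = 6.0
    roi_separation_mm: float = 20.0
    # clustering / decoding
    k_override: int | None = None
    synonym_groups: list = field(default_factory=list)
    subtraction_correction: str = "fwe_max"
    # simulation (used with run_pipeline(..., simulate=preset))
    sim_n_noise_foci: int = 5
    sim_db_studies: int = 120
    sim_rest_subjects: int = 6
    sim_rest_runs: int = 2
    sim_rest_timepoints: int = 120
    sim_block_rho: float = 0.5
    sim_global_amp: float = 0.5
    seed: int = 0

    def __post_init__(self):
        # normalise sequence fields so YAML round-trips compare equal
        self.extent_mm = tuple(float(v) for v in np.atleast_1d(self.extent_mm))
        self.mask_semi_axes_mm = tuple(
            float(v) for v in np.atleast_1d(self.mask_semi_axes_mm))

    def validate(self):
        for name, v, lo, hi in [("voxel_p", self.voxel_p, 0, 1),
                                ("fwe", self.fwe, 0, 1),
                                ("macm_fwe_p", self.macm_fwe_p, 0, 1),
                                ("rsfc_alpha", self.rsfc_alpha, 0, 1)]:
            if not (lo < v < hi):
                raise ValueError(f"{name} must lie in ({lo}, {hi}); got {v}")
        if self.decode_r < -1 or self.decode_r > 1:
            raise ValueError("decode_r must lie in [-1, 1]")
        if self.subtraction_extent_voxels < 0:
            raise ValueError("subtraction_extent_voxels must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed (< 2**31)."""
        return int(np.random.SeedSequence(
            [int(self.seed), zlib.crc32(stage.encode())]
        ).generate_state(1)[0] % (2**31))

    def make_grid(self) -> BrainGrid:
        return make_grid(self.voxel_size_mm, self.extent_mm,
                         {"type": "ellipsoid",
                          "semi_axes_mm": list(self.mask_semi_axes_mm)})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Execution context: config, run directory, lazily shared artifacts."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.dir = Path(config.output_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.grid = config.make_grid()
        self.cache: dict = {}
        self.log_path = self.dir / "run.log"

    # -- bookkeeping ------------------------------------------------------
    def stage_dir(self, stage: str) -> Path:
        d = self.dir / stage
        d.mkdir(exist_ok=True)
        return d

    def done(self, stage: str) -> bool:
        return (self.dir / stage / ".done").exists()

    def mark_done(self, stage: str) -> None:
        (self.dir / stage / ".done").write_text("ok\n")

    def log(self, stage: str, message: str) -> None:
        line = f"[{stage}] seed={self.cfg.stage_seed(stage)} {message}"
        logger.info(line)
        with open(self.log_path, "a") as fh:
            fh.write(line + "\n")

    # -- artifact helpers -------------------------------------------------
    def write_map(self, stage: str, name: str, vmap: VolumeMap) -> Path:
        p = self.stage_dir(stage) / f"{name}.nii.gz"
        write_volume(vmap, p)
        return p

    def read_map(self, stage: str, name: str, kind="other") -> VolumeMap:
        return read_volume(self.dir / stage / f"{name}.nii.gz", self.grid, kind)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(run: PipelineRun, preset: str) -> None:
    cfg = run.cfg
    d = run.stage_dir("simulate")
    world = gen_world_fixture(preset, cfg.seed)
    # persist the preset's grid definition so later single-stage
    # invocations reconstruct the same session grid
    with open(d / "grid.json", "w") as fh:
        json.dump({"preset": preset, **{k: list(v) if isinstance(v, tuple)
                                        else v
                                        for k, v in
                                        PRESET_GRID_SPEC[preset].items()}},
                  fh, indent=1)
    if not np.allclose(world.grid.voxel_size, run.grid.voxel_size) or \
            world.grid.shape != run.grid.shape:
        run.grid = world.grid  # preset owns the grid definition
    corpus = gen_foci_corpus(
        world, sum(GROUP_COUNTS[preset].values()),
        n_noise_foci=cfg.sim_n_noise_foci, group_counts=GROUP_COUNTS[preset],
    )
    corpus.save(d / "foci.tsv")
    db = gen_coordinate_db(world, cfg.sim_db_studies)
    save_database(db, d / "db_foci.tsv", d / "db_annotations.tsv")
    runs = gen_rest_runs(world, cfg.sim_rest_subjects, cfg.sim_rest_runs,
                         cfg.sim_rest_timepoints, block_rho=cfg.sim_block_rho,
                         global_amp=cfg.sim_global_amp)
    manifest_rows = []
    for r in runs:
        name = f"rest_{r.subject_id}_{r.run_id}.nii.gz"
        img = nib.Nifti1Image(r.series.astype(np.float32), run.grid.affine)
        nib.save(img, str(d / name))
        manifest_rows.append({"subject_id": r.subject_id, "run_id": r.run_id,
                              "tr_seconds": r.tr_seconds, "path": name})
    pd.DataFrame(manifest_rows).to_csv(d / "rest_manifest.tsv", sep="\t",
                                       index=False)
    with open(d / "ground_truth.json", "w") as fh:
        json.dump(world.ground_truth(), fh, indent=1)
    cfg.foci_path = str(d / "foci.tsv")
    cfg.db_foci_path = str(d / "db_foci.tsv")
    cfg.db_annotations_path = str(d / "db_annotations.tsv")
    cfg.rest_manifest_path = str(d / "rest_manifest.tsv")
    run.cache["world"] = world
    run.log("simulate", f"preset={preset} experiments={corpus.n_experiments} "
                        f"db_studies={len(db)} rest_runs={len(runs)}")


def _load_foci(run: PipelineRun) -> FociTable:
    if "foci" not in run.cache:
        if run.cfg.foci_path is None:
            raise PipelineError("ale", "no foci table (set foci_path or simulate)")
        run.cache["foci"] = load_foci_table(run.cfg.foci_path)
    return run.cache["foci"]


def stage_ale(run: PipelineRun) -> None:
    cfg = run.cfg
    foci = _load_foci(run)
    run.log("ale", f"voxel_p={cfg.voxel_p} fwe={cfg.fwe} "
                   f"iterations={cfg.ale_iterations}")
    results = {}
    jobs = {"pooled": foci}
    for g in foci.groups():
        if foci.by_group(g).n_experiments >= 2:
            jobs[g] = foci.by_group(g)
    for name, table in jobs.items():
        model = ALE(table.df, run.grid, bin_width=cfg.bin_width)
        res = model.fit(voxel_p=cfg.voxel_p, n_iterations=cfg.ale_iterations,
                        seed=cfg.stage_seed(f"ale:{name}"), fwe=cfg.fwe)
        results[name] = res
        run.write_map("ale", f"{name}_ale", res.ale_map)
        run.write_map("ale", f"{name}_z", res.z_map)
        run.write_map("ale", f"{name}_thresholded", res.thresholded_map)
        res.summary().to_csv(run.stage_dir("ale") / f"{name}_clusters.tsv",
                             sep="\t", index=False)
        meta = {"seed": res.seed, "iterations": cfg.ale_iterations,
                "voxel_p": cfg.voxel_p, "ale_cutoff": res.ale_cutoff,
                "extent_threshold_voxels": res.extent_threshold_voxels,
                "connectivity": 26}
        with open(run.stage_dir("ale") / f"{name}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)
    run.cache["ale_results"] = results


def _ale_results(run: PipelineRun) -> dict:
    if "ale_results" not in run.cache:
        stage_ale(run)
    return run.cache["ale_results"]


def stage_contrast(run: PipelineRun) -> None:
    cfg = run.cfg
    foci = _load_foci(run)
    groups = [g for g in foci.groups()
              if foci.by_group(g).n_experiments >= 2]
    d = run.stage_dir("contrast")
    if len(groups) < 2:
        run.log("contrast", "fewer than two eligible groups; skipped")
        (d / "skipped.txt").write_text("fewer than two eligible groups\n")
        return
    a, b = groups[0], groups[1]
    results = _ale_results(run)
    conj = conjunction(results[a].thresholded, results[b].thresholded,
                       results[a].ale_map, results[b].ale_map)
    run.write_map("contrast", "conjunction", conj)
    sub = ALESubtraction(foci.by_group(a), foci.by_group(b), run.grid,
                         bin_width=cfg.bin_width)
    sres = sub.fit(n_iterations=cfg.subtraction_iterations,
                   seed=cfg.stage_seed("contrast"), fwe=cfg.fwe,
                   extent_voxels=cfg.subtraction_extent_voxels,
                   correction=cfg.subtraction_correction)
    run.write_map("contrast", "subtraction_z", sres.z_map)
    run.write_map("contrast", "subtraction_thresholded", sres.thresholded_map)
    summary = sres.summary()
    if "sub_maxima" in summary.columns:
        summary = summary.drop(columns=["sub_maxima"])
    summary.to_csv(d / "subtraction_clusters.tsv", sep="\t", index=False)
    run.log("contrast", f"groups={a!r}-{b!r} "
                        f"extent={cfg.subtraction_extent_voxels}")
    run.cache["subtraction"] = sres


def stage_rois(run: PipelineRun) -> None:
    cfg = run.cfg
    res = _ale_results(run)["pooled"]
    rois = rois_from_results(res, radius_mm=cfg.roi_radius_mm,
                             min_separation_mm=cfg.roi_separation_mm)
    if len(rois) == 0:
        raise PipelineError("rois", "no ROIs survive thresholding/pruning")
    d = run.stage_dir("rois")
    roi_table(rois).to_csv(d / "rois.tsv", sep="\t", index=False)
    combined = np.zeros(run.grid.shape)
    for i, r in enumerate(rois):
        m = r.mask_array(run.grid)
        combined[m] = i + 1
        write_volume(VolumeMap(run.grid, m.astype(float)), d / f"{r.roi_id}.nii.gz")
    write_volume(VolumeMap(run.grid, combined), d / "rois_indexed.nii.gz")
    run.cache["rois"] = rois
    run.log("rois", f"n_rois={len(rois)} radius={cfg.roi_radius_mm} "
                    f"separation={cfg.roi_separation_mm}")


def _rois(run: PipelineRun) -> list:
    if "rois" not in run.cache:
        p = run.dir / "rois" / "rois.tsv"
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            run.cache["rois"] = [
                sphere_roi((r.x, r.y, r.z), run.cfg.roi_radius_mm, run.grid,
                           roi_id=r.roi_id, value=r.value)
                for r in df.itertuples()
            ]
        else:
            stage_rois(run)
    return run.cache["rois"]


def _database(run: PipelineRun):
    if "db" not in run.cache:
        if run.cfg.db_foci_path is None:
            raise PipelineError("macm", "no coordinate database configured")
        run.cache["db"] = load_database(run.cfg.db_foci_path,
                                        run.cfg.db_annotations_path)
    return run.cache["db"]


def stage_macm(run: PipelineRun) -> None:
    cfg = run.cfg
    db = _database(run)
    d = run.stage_dir("macm")
    unthresh = {}
    sel_rows = []
    for roi in _rois(run):
        model = MACM(db, roi, run.grid, fwhm_mm=cfg.macm_fwhm_mm)
        res = model.fit(n_null_iterations=cfg.macm_iterations,
                        seed=cfg.stage_seed(f"macm:{roi.roi_id}"),
                        fwe_p=cfg.macm_fwe_p)
        unthresh[roi.roi_id] = res.unthresholded_map
        run.write_map("macm", f"{roi.roi_id}_unthresholded",
                      res.unthresholded_map)
        if res.thresholded_map is not None:
            run.write_map("macm", f"{roi.roi_id}_thresholded",
                          res.thresholded_map)
        for s in res.selected_study_ids:
            sel_rows.append({"roi_id": roi.roi_id, "study_id": s})
    pd.DataFrame(sel_rows, columns=["roi_id", "study_id"]).to_csv(
        d / "selection.tsv", sep="\t", index=False)
    run.cache["macm_maps"] = unthresh
    run.log("macm", f"fwhm={cfg.macm_fwhm_mm} fwe_p={cfg.macm_fwe_p} "
                    f"iterations={cfg.macm_iterations}")


def _macm_maps(run: PipelineRun) -> dict:
    if "macm_maps" not in run.cache:
        maps = {}
        for roi in _rois(run):
            p = run.dir / "macm" / f"{roi.roi_id}_unthresholded.nii.gz"
            if not p.exists():
                stage_macm(run)
                return run.cache["macm_maps"]
            maps[roi.roi_id] = read_volume(p, run.grid, "ALE")
        run.cache["macm_maps"] = maps
    return run.cache["macm_maps"]


def _rest_runs(run: PipelineRun) -> list:
    if "rest_runs" not in run.cache:
        if run.cfg.rest_manifest_path is None:
            raise PipelineError("rsfc", "no rest manifest configured")
        mpath = Path(run.cfg.rest_manifest_path)
        manifest = pd.read_csv(mpath, sep="\t")
        runs = []
        for row in manifest.itertuples():
            img = nib.load(str(mpath.parent / row.path))
            runs.append(RestRun(grid=run.grid,
                                series=np.asarray(img.get_fdata(), float),
                                tr_seconds=float(row.tr_seconds),
                                subject_id=str(row.subject_id),
                                run_id=str(row.run_id)))
        run.cache["rest_runs"] = runs
    return run.cache["rest_runs"]


def stage_rsfc(run: PipelineRun) -> None:
    cfg = run.cfg
    runs = _rest_runs(run)
    d = run.stage_dir("rsfc")
    group_maps = {}
    for roi in _rois(run):
        model = GroupConnectivity(runs, roi,
                                  smoothing_fwhm=cfg.rsfc_smoothing_fwhm_mm)
        g = model.fit(alpha=cfg.rsfc_alpha,
                      n_permutations=cfg.rsfc_permutations,
                      seed=cfg.stage_seed(f"rsfc:{roi.roi_id}"))
        group_maps[roi.roi_id] = g.beta_map
        run.write_map("rsfc", f"{roi.roi_id}_group", g.beta_map)
        thr = VolumeMap(run.grid,
                        np.where(g.thresholded, g.t_map.data, 0.0), "tstat")
        run.write_map("rsfc", f"{roi.roi_id}_group_thresholded", thr)
        with open(d / f"{roi.roi_id}_meta.json", "w") as fh:
            json.dump({"n_subjects": g.n_subjects, "threshold": g.threshold,
                       "alpha": cfg.rsfc_alpha,
                       "model": "one-sample t, sign-flip max-height"},
                      fh, indent=1)
    run.cache["rsfc_maps"] = group_maps
    run.log("rsfc", f"alpha={cfg.rsfc_alpha} smoothing="
                    f"{cfg.rsfc_smoothing_fwhm_mm} runs={len(runs)}")


def _rsfc_maps(run: PipelineRun) -> dict:
    if "rsfc_maps" not in run.cache:
        maps = {}
        for roi in _rois(run):
            p = run.dir / "rsfc" / f"{roi.roi_id}_group.nii.gz"
            if not p.exists():
                stage_rsfc(run)
                return run.cache["rsfc_maps"]
            maps[roi.roi_id] = read_volume(p, run.grid, "correlation")
        run.cache["rsfc_maps"] = maps
    return run.cache["rsfc_maps"]


def stage_profile(run: PipelineRun) -> None:
    d = run.stage_dir("profile")
    pm_macm = crosscorr_matrix(_macm_maps(run), run.grid, modality="macm")
    pm_rsfc = crosscorr_matrix(_rsfc_maps(run), run.grid, modality="rsfc")
    pm_multi = multimodal_average(pm_rsfc, pm_macm)
    for pm in (pm_macm, pm_rsfc, pm_multi):
        pm.to_frame().to_csv(d / f"matrix_{pm.modality}.tsv", sep="\t")
    run.cache["profile_matrices"] = {
        "macm": pm_macm, "rsfc": pm_rsfc, "multimodal": pm_multi,
    }
    run.log("profile", f"n_rois={len(pm_multi.roi_ids)}")


def _profile_matrices(run: PipelineRun) -> dict:
    if "profile_matrices" not in run.cache:
        d = run.dir / "profile"
        if (d / "matrix_multimodal.tsv").exists():
            out = {}
            for mod in ("macm", "rsfc", "multimodal"):
                df = pd.read_csv(d / f"matrix_{mod}.tsv", sep="\t", index_col=0)
                out[mod] = ProfileMatrix(list(df.columns), df.to_numpy(), mod)
            run.cache["profile_matrices"] = out
        else:
            stage_profile(run)
    return run.cache["profile_matrices"]


def stage_cluster(run: PipelineRun) -> None:
    cfg = run.cfg
    d = run.stage_dir("cluster")
    pms = _profile_matrices(run)
    # per-modality dendrograms exported for inspection; the multimodal
    # matrix provides the final solution
    for mod in ("macm", "rsfc"):
        try:
            res = CliqueModel(pms[mod]).fit()
            (d / f"dendrogram_{mod}.newick").write_text(res.to_newick() + "\n")
        except ValueError:
            pass
    res = CliqueModel(pms["multimodal"]).fit(override=cfg.k_override)
    (d / "dendrogram_multimodal.newick").write_text(res.to_newick() + "\n")
    res.selection_metrics.to_csv(d / "selection_metrics.tsv", sep="\t",
                                 index=False)
    res.summary().to_csv(d / "cliques.tsv", sep="\t", index=False)
    with open(d / "linkage.json", "w") as fh:
        json.dump({"linkage": res.linkage.tolist(), "k": res.k,
                   "roi_ids": res.model.pm.roi_ids}, fh, indent=1)
    run.cache["cliques"] = res
    run.log("cluster", f"k={res.k} override={cfg.k_override}")


def _cliques(run: PipelineRun):
    if "cliques" not in run.cache:
        p = run.dir / "cluster" / "cliques.tsv"
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            pms = _profile_matrices(run)
            res = CliqueModel(pms["multimodal"]).fit(
                override=int(df["clique"].nunique()))
            run.cache["cliques"] = res
        else:
            stage_cluster(run)
    return run.cache["cliques"]


def stage_decode(run: PipelineRun) -> None:
    cfg = run.cfg
    db = _database(run)
    d = run.stage_dir("decode")
    cliques = _cliques(run)
    macm_maps = _macm_maps(run)
    term_maps = {t: term_association_map(db, t, run.grid,
                                         fwhm_mm=cfg.macm_fwhm_mm)
                 for t in db.terms}
    frames = []
    for c in cliques.cliques:
        cmap = clique_mean_map(cliques.members(c), macm_maps)
        run.write_map("decode", f"clique{c}_mean", cmap)
        table = decode_terms(cmap, term_maps, r_threshold=cfg.decode_r,
                             synonym_groups=cfg.synonym_groups)
        table.insert(0, "clique", c)
        frames.append(table)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["clique", "term", "r"])
    out.to_csv(d / "decoding.tsv", sep="\t", index=False)
    run.cache["decoding"] = out
    run.log("decode", f"r_threshold={cfg.decode_r} n_terms={len(db.terms)}")


_STAGE_FUNCS = {
    "ale": stage_ale, "contrast": stage_contrast, "rois": stage_rois,
    "macm": stage_macm, "rsfc": stage_rsfc, "profile": stage_profile,
    "cluster": stage_cluster, "decode": stage_decode,
}


def run_pipeline(config: PipelineConfig, simulate: str | None = None,
                 force: bool = False) -> Path:
    """Execute all stages in order; returns the run directory.

    ``simulate`` names a preset ("tiny" / "paper-like") to generate inputs
    first.  Completed stages (``.done`` marker present) are skipped unless
    ``force``.  On stage failure, partial outputs are retained with a
    FAILED marker and :class:`PipelineError` is raised.
    """
    if simulate is not None:
        # the preset owns the grid definition; align the config so resumed
        # runs reconstruct the same grid
        if simulate not in PRESET_GRID_SPEC:
            raise ValueError(
                f"unknown preset {simulate!r}; available: "
                f"{sorted(PRESET_GRID_SPEC)}"
            )
        for k, v in PRESET_GRID_SPEC[simulate].items():
            setattr(config, k, v)
    run = PipelineRun(config)
    t0 = time.time()
    stage = "simulate"
    try:
        if simulate is not None and (force or not run.done("simulate")):
            stage_simulate(run, simulate)
            run.mark_done("simulate")
        elif simulate is not None:
            d = run.dir / "simulate"
            config.foci_path = str(d / "foci.tsv")
            config.db_foci_path = str(d / "db_foci.tsv")
            config.db_annotations_path = str(d / "db_annotations.tsv")
            config.rest_manifest_path = str(d / "rest_manifest.tsv")
        for stage in STAGES[1:]:
            if run.done(stage) and not force:
                run.log(stage, "skipped (outputs present)")
                continue
            _STAGE_FUNCS[stage](run)
            run.mark_done(stage)
    except PipelineError:
        (run.dir / "FAILED").write_text("see run.log\n")
        raise
    except Exception as exc:
        (run.dir / "FAILED").write_text(f"{exc}\n")
        raise PipelineError(stage, str(exc)) from exc
    _write_manifest(run)
    write_report(run.dir, config)
    run.log("pipeline", f"completed in {time.time() - t0:.1f}s")
    return run.dir


def _write_manifest(run: PipelineRun) -> None:
    artifacts = {}
    for p in sorted(run.dir.rglob("*")):
        if p.is_file() and p.name not in (".done", "manifest.json", "run.log"):
            artifacts[str(p.relative_to(run.dir))] = _sha256(p)
    manifest = {
        "package_version": __version__,
        "seed": run.cfg.seed,
        "config": dataclasses.asdict(run.cfg),
        "artifacts": artifacts,
    }
    with open(run.dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def write_report(run_directory, config: PipelineConfig | None = None) -> Path:
    """Collect the human-readable report: cluster table (Table-2 layout),
    ROI table, matrices, clique assignments, decoding tables.

    Raises :class:`PipelineError` listing missing artifacts when the run is
    incomplete.
    """
    run_dir = Path(run_directory)
    required = {
        "ale/pooled_clusters.tsv": "pooled cluster table",
        "rois/rois.tsv": "ROI table",
        "profile/matrix_multimodal.tsv": "multimodal matrix",
        "cluster/cliques.tsv": "clique assignment",
        "decode/decoding.tsv": "decoding table",
    }
    missing = [k for k in required if not (run_dir / k).exists()]
    if missing:
        raise PipelineError("report", f"missing artifacts: {missing}")
    d = run_dir / "report"
    d.mkdir(exist_ok=True)
    clusters = pd.read_csv(run_dir / "ale" / "pooled_clusters.tsv", sep="\t")
    clusters.to_csv(d / "cluster_table.tsv", sep="\t", index=False)
    for src, dst in [("rois/rois.tsv", "roi_table.tsv"),
                     ("profile/matrix_rsfc.tsv", "matrix_rsfc.tsv"),
                     ("profile/matrix_macm.tsv", "matrix_macm.tsv"),
                     ("profile/matrix_multimodal.tsv", "matrix_multimodal.tsv"),
                     ("cluster/cliques.tsv", "cliques.tsv"),
                     ("cluster/selection_metrics.tsv", "selection_metrics.tsv"),
                     ("decode/decoding.tsv", "decoding.tsv")]:
        if (run_dir / src).exists():
            (d / dst).write_text((run_dir / src).read_text())
    return d
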