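"""Pipeline configuration and the end-to-end runner.

Stages: synthesize (optional) -> preprocess -> voxel networks -> graph
metrics over the threshold sweep -> group inference (small-worldness sweep
contrast, nodal degree contrast, duration-efficiency partial correlation)
-> ROI networks -> task GLM -> rest-task interaction.  Every numeric output
derives deterministically from the configuration and its seed; a manifest
records each written file together with a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (graphmetrics, inference, io, preprocess, resttask, roinet,
               synthcohort, voxelnet)
from . import taskglm as taskglm_mod
from .geometry import make_geometry

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResult"]

STAGES = ("synth", "preprocess", "voxelnet", "metrics", "contrast", "roinet",
          "taskglm", "interaction")


@dataclass
class PipelineConfig:
    """All tunable constants of the analysis, with the printed defaults.

    The threshold sweep runs 0.36-0.60 in 0.01 steps; rewired nulls use 10
    swaps per edge; the task GLM high-pass cut-off is 128 s with cluster
    extent > 20 voxels; ROI spheres are 12 mm in diameter.
    """

    tr_s: float = 2.0
    low_hz: float = 0.01
    high_hz: float = 0.08
    t_min: float = 0.36
    t_max: float = 0.60
    t_step: float = 0.01
    swaps_per_edge: float = 10.0
    n_null: int = 20
    q_sweep: float = 0.05
    q_nodes: float = 0.05
    q_edges: float = 0.05
    q_task: float = 0.01
    min_cluster_nodes: int = 3
    min_cluster_task: int = 20
    sphere_diameter_mm: float = 12.0
    hp_cutoff_s: float = 128.0
    seed: int = 0
    # synthetic-cohort geometry and sizes (used when no input dir is given)
    grid_dims: tuple = (7, 7, 6)
    n_regions: int = 10
    spacing_mm: float = 3.0
    n_per_group: int = 16
    n_rest_vols: int = 150
    n_task_vols: int = 240
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("require 0 < low_hz < high_hz")
        if self.t_step <= 0 or self.t_min >= self.t_max:
            raise ValueError("threshold grid must be ascending")
        for name in ("tr_s", "swaps_per_edge", "sphere_diameter_mm",
                     "hp_cutoff_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def t_grid(self) -> np.ndarray:
        return voxelnet.default_threshold_grid(self.t_min, self.t_max,
                                               self.t_step)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "grid_dims" in raw:
            raw["grid_dims"] = tuple(raw["grid_dims"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_dims"] = list(d["grid_dims"])
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    cohort: synthcohort.Cohort
    metrics: pd.DataFrame
    t_low: float
    sweep: inference.SweepContrast
    degree_contrast: inference.NodalContrast
    degrees_at_best: dict                      # group -> subjects x nodes
    efficiency_partial: tuple | None           # (r, p) duration vs E_glob
    rois: list
    edge_tests: pd.DataFrame | None
    edge_duration: pd.DataFrame | None
    task_group: object | None
    interaction: pd.DataFrame | None
    craving_test: inference.StatResult | None
    outputs: dict = field(default_factory=dict)


def _denoise_all(cohort, cfg):
    g = cohort.geometry
    out = {}
    for s in cohort.subjects:
        out[s.id] = preprocess.preprocess_run(
            s.rest_run.data, g.gray_mask, g.wm_mask, g.vent_mask,
            s.motion_params, s.rest_run.tr_s, cfg.low_hz, cfg.high_hz,
        )
    return out


def _connected_grid(corrs, grid):
    """Thresholds at which every subject's graph is fully connected."""
    keep = []
    for t in grid:
        if all(voxelnet.largest_component_fraction(voxelnet.binarize(c, t)) == 1.0
               for c in corrs):
            keep.append(t)
    return np.asarray(keep)


def run_pipeline(
    config: PipelineConfig,
    input_dir=None,
    out_dir=None,
    stop_after: str | None = None,
) -> PipelineResult:
    """Execute the full analysis; optionally stop after a named stage.

    With no ``input_dir`` a cohort is synthesized from the configuration.
    When ``out_dir`` is given, every stage writes its tables/maps there and
    a manifest records the files with the configuration hash.
    """
    timings = {}

    def tick(stage, t0):
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %-12s %6.2fs", stage, timings[stage])

    def done(stage):
        return stop_after == stage

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    outputs = {}

    def emit(name, frame):
        if out is not None:
            path = out / name
            frame.to_csv(path, sep="\t", index=False)
            outputs[name] = str(path)

    # --- synth / load ------------------------------------------------------
    t0 = time.perf_counter()
    if input_dir is None:
        geometry = make_geometry(config.grid_dims, config.n_regions,
                                 config.spacing_mm, seed=config.seed)
        truth = synthcohort.GroundTruth(seed=config.seed, **config.truth)
        cohort = synthcohort.simulate_cohort(
            geometry, truth, n_per_group=config.n_per_group,
            n_rest_vols=config.n_rest_vols, n_task_vols=config.n_task_vols,
            tr_s=config.tr_s, seed=config.seed)
    else:
        cohort = io.load_cohort(input_dir)
    geometry = cohort.geometry
    tick("synth", t0)
    empty = PipelineResult(
        cohort=cohort, metrics=pd.DataFrame(), t_low=np.nan, sweep=None,
        degree_contrast=None, degrees_at_best={}, efficiency_partial=None,
        rois=[], edge_tests=None, edge_duration=None, task_group=None,
        interaction=None, craving_test=None, outputs=outputs)
    if done("synth"):
        if out is not None:
            io.write_cohort(cohort, out / "cohort")
        return empty

    # --- preprocess --------------------------------------------------------
    t0 = time.perf_counter()
    denoised = _denoise_all(cohort, config)
    tick("preprocess", t0)
    if done("preprocess"):
        return empty

    # --- voxel networks ----------------------------------------------------
    t0 = time.perf_counter()
    corrs = {sid: voxelnet.correlation_matrix(x) for sid, x in denoised.items()}
    grid = config.t_grid
    t_low = voxelnet.find_lower_bound_threshold(list(corrs.values()), grid)
    # connectivity is monotone in T, so the fully connected part of the
    # sweep is everything up to t_low
    usable = _connected_grid(list(corrs.values()), grid[grid <= t_low])
    if usable.size == 0:
        raise RuntimeError(
            "no sweep threshold yields fully connected graphs for every "
            "subject; lower t_min or inspect the input runs"
        )
    empty.t_low = t_low
    tick("voxelnet", t0)
    if done("voxelnet"):
        return empty

    # --- graph metrics over the sweep -------------------------------------
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(config.seed + 1)
    rows = []
    degrees = {}  # (sid, T) -> degree vector
    subj_seeds = {s.id: child for s, child in
                  zip(cohort.subjects, ss.spawn(len(cohort.subjects)))}
    for s in cohort.subjects:
        null_seeds = subj_seeds[s.id].spawn(len(usable))
        for t, nseed in zip(usable, null_seeds):
            adj = voxelnet.binarize(corrs[s.id], t)
            sw = graphmetrics.small_world(
                adj, n_null=config.n_null,
                swaps_per_edge=config.swaps_per_edge,
                seed=int(nseed.generate_state(1)[0]) % (2 ** 31))
            d = graphmetrics.degree(adj)
            degrees[(s.id, float(t))] = d
            rows.append({
                "subject": s.id, "group": s.group, "threshold": float(t),
                "C": sw.C, "L": sw.L, "C_rand": sw.C_rand, "L_rand": sw.L_rand,
                "gamma": sw.gamma, "lambda": sw.lam, "sigma": sw.sigma,
                "E_glob": graphmetrics.global_efficiency(adj),
            })
    metrics = pd.DataFrame(rows)
    empty.metrics = metrics
    emit("metrics.tsv", metrics)
    tick("metrics", t0)
    if done("metrics"):
        return empty

    # --- inference ---------------------------------------------------------
    t0 = time.perf_counter()
    pivot = metrics.pivot_table(index=["group", "subject"], columns="threshold",
                                values="sigma").loc[:, usable]
    sig_a = pivot.loc["CHU"].to_numpy()
    sig_b = pivot.loc["NDU"].to_numpy()
    sweep = inference.sweep_contrast(sig_a, sig_b, usable, q=config.q_sweep)
    best_t = sweep.best_threshold
    deg = {
        grp: np.stack([degrees[(s.id, best_t)]
                       for s in cohort.group(grp)]).astype(float)
        for grp in ("CHU", "NDU")
    }
    contrast = inference.nodal_degree_contrast(
        deg["CHU"], deg["NDU"], geometry, q=config.q_nodes,
        min_cluster=config.min_cluster_nodes)
    chu = cohort.group("CHU")
    eff = metrics[(metrics.group == "CHU")
                  & (metrics.threshold == best_t)].set_index("subject")
    e_glob = np.array([eff.loc[s.id, "E_glob"] for s in chu])
    duration = np.array([s.duration_months for s in chu])
    age = np.array([s.age_years for s in chu])
    efficiency_partial = inference.partial_corr(e_glob, duration, covariates=age)
    craving = None
    pre = [s.craving_pre for s in chu if s.craving_pre is not None]
    post = [s.craving_post for s in chu if s.craving_post is not None]
    if len(pre) >= 2 and len(pre) == len(post):
        craving = inference.paired_t(pre, post)
    empty.sweep = sweep
    empty.degree_contrast = contrast
    empty.degrees_at_best = deg
    empty.efficiency_partial = efficiency_partial
    empty.craving_test = craving
    emit("sweep_contrast.tsv", sweep.table)
    if out is not None:
        io.write_map(contrast.t, geometry, out / "degree_contrast_t.nii")
        outputs["degree_contrast_t.nii"] = str(out / "degree_contrast_t.nii")
        clusters = [{
            "size": c.size, "peak_coord_mm": list(c.peak_coord_mm),
            "region": c.region, "peak_t": c.peak_t,
            "mean_degree_CHU": c.mean_degree_a,
            "mean_degree_NDU": c.mean_degree_b,
        } for c in contrast.clusters]
        (out / "degree_clusters.json").write_text(
            json.dumps({
                "best_threshold": best_t,
                "significant_range": sweep.significant_range,
                "duration_efficiency_partial_r": efficiency_partial[0],
                "duration_efficiency_partial_p": efficiency_partial[1],
                "clusters": clusters,
            }, indent=2), encoding="utf-8")
    tick("contrast", t0)
    if done("contrast"):
        return empty

    # --- ROI networks ------------------------------------------------------
    t0 = time.perf_counter()
    rois = roinet.select_rois(contrast, geometry,
                              min_cluster=config.min_cluster_nodes,
                              sphere_diameter_mm=config.sphere_diameter_mm)
    edge_tests = edge_duration = None
    if len(rois) >= 2:
        weights = {}
        for grp in ("CHU", "NDU"):
            mats = []
            for s in cohort.group(grp):
                ts = roinet.roi_timeseries(denoised[s.id], rois)
                mats.append(roinet.edge_vector(roinet.weighted_network(ts)))
            weights[grp] = np.stack(mats)
        edge_tests = roinet.edgewise_group_test(
            weights["CHU"], weights["NDU"], q=config.q_edges)
        edge_duration = roinet.edge_duration_correlation(
            weights["CHU"], duration, age)
        roi_table = pd.DataFrame([{
            "label": r.label, "region": r.region,
            "x_mm": r.center_mm[0], "y_mm": r.center_mm[1],
            "z_mm": r.center_mm[2], "n_voxels": len(r.members),
        } for r in rois])
        emit("rois.tsv", roi_table)
        emit("edge_tests.tsv", edge_tests)
        emit("edge_duration.tsv", edge_duration)
    empty.rois = rois
    empty.edge_tests = edge_tests
    empty.edge_duration = edge_duration
    tick("roinet", t0)
    if done("roinet"):
        return empty

    # --- task GLM ----------------------------------------------------------
    t0 = time.perf_counter()
    task_group = None
    contrast_maps = {}
    task_subjects = [s for s in cohort.subjects if s.task_run is not None]
    for s in task_subjects:
        design = taskglm_mod.build_design(
            s.task_run.events, s.task_run.data.shape[1], s.task_run.tr_s,
            hp_cutoff_s=config.hp_cutoff_s)
        nodes = s.task_run.data[geometry.gray_mask]
        cmap = taskglm_mod.fit_contrast(nodes, design)
        contrast_maps[s.id] = cmap.estimate
    if len(contrast_maps) >= 2:
        stacked = np.stack(list(contrast_maps.values()))
        task_group = taskglm_mod.group_contrast(
            stacked, geometry, q=config.q_task,
            min_cluster=config.min_cluster_task)
        if out is not None:
            io.write_map(task_group.t, geometry, out / "task_contrast_t.nii")
            outputs["task_contrast_t.nii"] = str(out / "task_contrast_t.nii")
    empty.task_group = task_group
    tick("taskglm", t0)
    if done("taskglm"):
        return empty

    # --- rest-task interaction --------------------------------------------
    t0 = time.perf_counter()
    interaction = None
    chu_with_task = [s for s in chu if s.id in contrast_maps]
    if rois and len(chu_with_task) >= 4:
        deg_maps = np.stack([degrees[(s.id, best_t)]
                             for s in chu_with_task]).astype(float)
        con_maps = np.stack([contrast_maps[s.id] for s in chu_with_task])
        craving_change = None
        if all(s.craving_pre is not None for s in chu_with_task):
            craving_change = np.array([
                s.craving_post - s.craving_pre for s in chu_with_task])
        interaction = resttask.interaction_table(
            rois, deg_maps, con_maps, craving_change)
        emit("interaction.tsv", interaction)
    empty.interaction = interaction
    tick("interaction", t0)

    if out is not None:
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "node_indexing": "0-based over gray voxels, C-order lattice",
            "outputs": sorted(outputs),
            "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                           encoding="utf-8")
    return empty
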