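"""Synthetic two-group fMRI cohort with known ground truth.

The generator emulates the statistical structure the network analysis
assumes: block-structured inter-regional correlation with group-specific hub
regions, a dependence-duration covariate coupled to network connectivity (and
hence efficiency), and cue-reactivity activation coupled to resting nodal
degree.  Region signals follow a one-factor latent model

    u_r(t) = a_r f(t) + sqrt(1 - a_r^2) e_r(t),

so the implied region-by-region correlation is a_r a_s off the diagonal:
hub regions (elevated a_r) couple more strongly to every other region.  The
factor construction is O(N); the covariance is implied, never inverted.
Voxel signals add white noise, a shared sum-of-slow-cosines drift (all power
below 0.01 Hz, so the analysis bandpass provably removes it), and shared
white-matter/ventricle confound components that the nuisance regression can
recover from the tissue masks.

Defaults encode the study conditions: 16 subjects per group, 150-volume rest
runs and 240-volume task runs at TR 2 s, 48-trial event schedules (2 s
stimuli, 4-12 s jittered ISI), dependence duration uniform on 19-182 months,
age uniform on 25-49 years, craving scores centred on 0.6 pre and 5.5 post.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import Geometry, make_geometry
from . import preprocess, voxelnet, graphmetrics, taskglm

__all__ = [
    "GroundTruth",
    "RestRun",
    "TaskRun",
    "Subject",
    "Cohort",
    "make_geometry",
    "make_event_schedule",
    "simulate_rest_run",
    "simulate_task_run",
    "simulate_cohort",
]

DURATION_RANGE_MONTHS = (19.0, 182.0)
AGE_RANGE_YEARS = (25.0, 49.0)


@dataclass
class GroundTruth:
    """Injected effects the analysis should recover, plus nuisance levels.

    ``duration_efficiency_slope`` scales every region coupling of a patient
    multiplicatively with standardized dependence duration (negative slope:
    longer use, weaker connectivity, lower efficiency).
    ``degree_activation_slope`` sets the heroin-minus-neutral amplitude gain
    per unit standardized resting degree in the coupling regions.
    """

    hub_regions_per_group: dict = field(
        default_factory=lambda: {"CHU": [2, 3], "NDU": [5, 6]}
    )
    duration_efficiency_slope: float = -0.1
    degree_activation_slope: float = 0.5
    noise_sd: float = 0.7
    seed: int = 0
    # latent coupling structure
    base_coupling: float = 0.35
    hub_coupling: float = 0.9
    global_coupling: float = 0.7  # unremoved global signal: correlation floor
    drift_amp: float = 1.0
    confound_amp: float = 0.3
    # task model
    coupling_regions: list | None = None  # defaults to the CHU hub regions
    heroin_amp: float = 1.2
    neutral_amp: float = 0.8
    task_noise_sd: float = 1.0
    degree_center: float = 90.0
    degree_scale: float = 40.0
    degree_threshold: float = 0.40  # threshold at which coupling degree is read
    # craving model (a stand-in: the craving distribution across subjects is
    # not constrained by the analysis; flagged in output metadata)
    craving_pre_mean: float = 0.6
    craving_pre_sd: float = 1.4
    craving_shift: float = 4.9
    craving_slope: float = 1.5
    craving_noise_sd: float = 1.0

    def to_metadata(self) -> dict:
        meta = asdict(self)
        meta["craving_model_is_stand_in"] = True
        return meta


@dataclass
class RestRun:
    data: np.ndarray          # n_total_voxels x n_vols
    tr_s: float
    motion_params: np.ndarray  # n_vols x 6
    confound_sources: dict = field(default_factory=dict)


@dataclass
class TaskRun:
    data: np.ndarray          # n_total_voxels x n_vols
    tr_s: float
    events: pd.DataFrame


@dataclass
class Subject:
    id: str
    group: str                # "CHU" or "NDU"
    age_years: float
    duration_months: float | None
    dosage_g: float | None
    craving_pre: float | None
    craving_post: float | None
    rest_run: RestRun
    task_run: TaskRun | None
    motion_params: np.ndarray


@dataclass
class Cohort:
    geometry: Geometry
    truth: GroundTruth
    subjects: list
    seed: int

    def phenotype(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append({
                "subject": s.id, "group": s.group, "age": s.age_years,
                "duration_months": s.duration_months, "dosage": s.dosage_g,
                "craving_pre": s.craving_pre, "craving_post": s.craving_post,
            })
        return pd.DataFrame(rows)

    def group(self, name: str) -> list:
        return [s for s in self.subjects if s.group == name]


def _duration_z(duration_months: float) -> float:
    lo, hi = DURATION_RANGE_MONTHS
    return (duration_months - (lo + hi) / 2.0) / ((hi - lo) / 2.0)


def _region_loadings(
    geometry: Geometry,
    truth: GroundTruth,
    group: str,
    duration_months: float | None,
) -> tuple[np.ndarray, float]:
    """Region factor loadings and the effective global-signal coupling.

    For patients, the whole coupling structure (region loadings and global
    coupling alike) is scaled by 1 + slope * standardized duration, so that
    connection density -- and with it global efficiency -- co-varies with
    dependence duration at the requested sign.
    """
    n_regions = geometry.n_regions
    a = np.full(n_regions, truth.base_coupling, dtype=float)
    hubs = truth.hub_regions_per_group.get(group, [])
    for r in hubs:
        if not 0 <= r < n_regions:
            raise ValueError(f"hub region {r} outside 0..{n_regions - 1}")
        a[r] = truth.hub_coupling
    bad = np.nonzero(np.abs(a) >= 1.0)[0]
    if bad.size:
        raise ValueError(
            f"region block {bad.tolist()}: implied correlation is not "
            f"positive definite (|coupling| >= 1)"
        )
    gamma = truth.global_coupling
    if group == "CHU" and duration_months is not None:
        scale = 1.0 + truth.duration_efficiency_slope * _duration_z(duration_months)
        a = np.clip(a * scale, 0.0, 0.97)
        gamma = gamma * scale
    return a, gamma


def _smooth_motion(rng: np.random.Generator, n_vols: int) -> np.ndarray:
    """Six slowly drifting rigid-body parameter series (mm / degrees)."""
    steps = rng.normal(scale=0.02, size=(n_vols, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(9) / 9.0
    smooth = np.apply_along_axis(
        lambda s: np.convolve(s, kernel, mode="same"), 0, walk
    )
    return smooth


def _slow_drift(rng: np.random.Generator, n_vols: int, tr_s: float,
                amp: float) -> np.ndarray:
    """Sum of cosines with frequencies strictly below 0.01 Hz."""
    t = np.arange(n_vols) * tr_s
    drift = np.zeros(n_vols)
    for _ in range(3):
        f = rng.uniform(0.002, 0.008)
        phase = rng.uniform(0, 2 * np.pi)
        drift += amp * np.cos(2 * np.pi * f * t + phase)
    return drift


def simulate_rest_run(
    geometry: Geometry,
    truth: GroundTruth,
    subject_covariates: dict,
    n_vols: int = 150,
    tr_s: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
) -> RestRun:
    """One subject's resting run over the full voxel lattice.

    ``subject_covariates`` must carry ``group`` and, for patients,
    ``duration_months``.  Gray voxels receive their region's latent signal
    plus white noise, the shared slow drift, and shared WM/ventricle
    confound components; WM and ventricle voxels carry their confound source
    so the preprocessing can extract it from the masks.
    """
    if n_vols < 20:
        raise ValueError("need n_vols >= 20")
    rng = np.random.default_rng(seed)
    group = subject_covariates["group"]
    a, gamma = _region_loadings(geometry, truth, group,
                                subject_covariates.get("duration_months"))
    n_regions = geometry.n_regions
    f = rng.standard_normal(n_vols)
    e = rng.standard_normal((n_regions, n_vols))
    u = a[:, None] * f + np.sqrt(1.0 - a ** 2)[:, None] * e
    g_signal = rng.standard_normal(n_vols)  # global signal, never regressed
    wm_source = rng.standard_normal(n_vols)
    vent_source = rng.standard_normal(n_vols)
    drift = _slow_drift(rng, n_vols, tr_s, truth.drift_amp)
    data = np.zeros((geometry.n_total, n_vols))
    gray_idx = np.nonzero(geometry.gray_mask)[0]
    regions = geometry.node_regions
    noise = rng.standard_normal((gray_idx.size, n_vols)) * truth.noise_sd
    # shared (equal-loading) drift and confound leakage keeps same-region
    # voxels perfectly correlated in the noise-free limit
    shared = (gamma * g_signal + drift
              + truth.confound_amp * (wm_source + vent_source))
    data[gray_idx] = u[regions] + noise + shared
    wm_idx = np.nonzero(geometry.wm_mask)[0]
    vent_idx = np.nonzero(geometry.vent_mask)[0]
    data[wm_idx] = wm_source + 0.2 * rng.standard_normal((wm_idx.size, n_vols)) + drift
    data[vent_idx] = vent_source + 0.2 * rng.standard_normal((vent_idx.size, n_vols)) + drift
    motion = _smooth_motion(rng, n_vols)
    return RestRun(
        data=data, tr_s=tr_s, motion_params=motion,
        confound_sources={"wm": wm_source, "vent": vent_source, "drift": drift},
    )


def make_event_schedule(
    n_trials: int = 48,
    stim_dur_s: float = 2.0,
    isi_min_s: float = 4.0,
    isi_max_s: float = 12.0,
    seed: int | np.random.SeedSequence = 0,
    fit_total_s: float | None = None,
) -> pd.DataFrame:
    """Randomized event-related schedule of heroin/neutral trials.

    Each trial is a ``stim_dur_s`` stimulus followed by a uniform
    ``isi_min_s``-``isi_max_s`` crosshair interval; condition labels are a
    random permutation of an (as equal as possible) heroin/neutral split.
    With the defaults, the expected total duration is 48 * (2 + 8) = 480 s.
    When ``fit_total_s`` is given the jitters are rescaled so the schedule
    fills that acquisition window exactly (as constrained stimulus-delivery
    protocols do), keeping every stimulus inside the run.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if isi_min_s > isi_max_s:
        raise ValueError("isi_min_s must not exceed isi_max_s")
    rng = np.random.default_rng(seed)
    half = n_trials // 2
    conditions = np.array(["heroin"] * (n_trials - half) + ["neutral"] * half)
    conditions = conditions[rng.permutation(n_trials)]
    isis = rng.uniform(isi_min_s, isi_max_s, size=n_trials)
    if fit_total_s is not None:
        slack = fit_total_s - n_trials * stim_dur_s
        if slack <= 0:
            raise ValueError("fit_total_s too short for the stimuli alone")
        isis = isis * (slack / isis.sum())
    onsets = np.concatenate([[0.0], np.cumsum(stim_dur_s + isis)[:-1]])
    return pd.DataFrame({
        "onset_s": onsets,
        "duration_s": np.full(n_trials, float(stim_dur_s)),
        "condition": conditions,
    })


def simulate_task_run(
    geometry: Geometry,
    truth: GroundTruth,
    resting_degree_per_region: np.ndarray,
    events: pd.DataFrame,
    n_vols: int = 240,
    tr_s: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
) -> TaskRun:
    """One subject's cue-reactivity run.

    In the designated coupling regions the heroin-minus-neutral amplitude is
    baseline plus ``degree_activation_slope`` times the standardized resting
    degree of that region; elsewhere the baseline contrast applies.  Event
    overlap or overrun raises.
    """
    rng = np.random.default_rng(seed)
    regressors = taskglm.convolve_events(events, n_vols, tr_s)  # validates events
    x_heroin = regressors.get("heroin", pd.Series(np.zeros(n_vols))).to_numpy()
    x_neutral = regressors.get("neutral", pd.Series(np.zeros(n_vols))).to_numpy()
    deg = np.asarray(resting_degree_per_region, dtype=float)
    n_regions = geometry.n_regions
    if deg.size != n_regions:
        raise ValueError("resting_degree_per_region length != number of regions")
    coupling = truth.coupling_regions
    if coupling is None:
        coupling = truth.hub_regions_per_group.get("CHU", [])
    z = (deg - truth.degree_center) / truth.degree_scale
    amp_h = np.full(n_regions, truth.heroin_amp)
    for r in coupling:
        amp_h[r] = truth.heroin_amp + truth.degree_activation_slope * z[r]
    amp_n = np.full(n_regions, truth.neutral_amp)
    drift = _slow_drift(rng, n_vols, tr_s, truth.drift_amp)
    data = np.zeros((geometry.n_total, n_vols))
    gray_idx = np.nonzero(geometry.gray_mask)[0]
    regions = geometry.node_regions
    signal = amp_h[regions, None] * x_heroin + amp_n[regions, None] * x_neutral
    noise = rng.standard_normal((gray_idx.size, n_vols)) * truth.task_noise_sd
    data[gray_idx] = signal + noise + drift
    other = ~geometry.gray_mask
    data[other] = rng.standard_normal((int(other.sum()), n_vols)) * truth.task_noise_sd
    return TaskRun(data=data, tr_s=tr_s, events=events)


def _analysis_region_degree(
    geometry: Geometry,
    rest: RestRun,
    truth: GroundTruth,
) -> tuple[np.ndarray, np.ndarray]:
    """Region-mean nodal degree of a denoised rest run at the coupling threshold."""
    nodes = preprocess.preprocess_run(
        rest.data, geometry.gray_mask, geometry.wm_mask, geometry.vent_mask,
        rest.motion_params, rest.tr_s,
    )
    corr = voxelnet.correlation_matrix(nodes)
    adj = voxelnet.binarize(corr, truth.degree_threshold)
    d = graphmetrics.degree(adj).astype(float)
    regions = geometry.node_regions
    region_deg = np.array([
        d[regions == r].mean() for r in range(geometry.n_regions)
    ])
    return region_deg, d


def simulate_cohort(
    geometry: Geometry,
    truth: GroundTruth,
    n_per_group: int = 16,
    n_rest_vols: int = 150,
    n_task_vols: int = 240,
    tr_s: float = 2.0,
    seed: int = 0,
) -> Cohort:
    """Generate the full two-group cohort.

    Patients (CHU) get a dependence duration, a cue-reactivity run whose
    activation is coupled to their analysed resting degree, and pre/post
    craving scores; controls (NDU) get rest runs only.  Everything derives
    deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    subjects = []
    groups = ["CHU"] * n_per_group + ["NDU"] * n_per_group
    children = ss.spawn(len(groups))
    coupling = truth.coupling_regions
    if coupling is None:
        coupling = truth.hub_regions_per_group.get("CHU", [])
    for i, (group, child) in enumerate(zip(groups, children)):
        streams = child.spawn(5)
        rng = np.random.default_rng(streams[0])
        age = rng.uniform(*AGE_RANGE_YEARS)
        duration = rng.uniform(*DURATION_RANGE_MONTHS) if group == "CHU" else None
        dosage = rng.uniform(0.2, 1.5) if group == "CHU" else None
        cov = {"group": group, "age": age, "duration_months": duration}
        rest = simulate_rest_run(geometry, truth, cov, n_rest_vols, tr_s,
                                 seed=streams[1])
        task = None
        craving_pre = craving_post = None
        if group == "CHU":
            region_deg, _ = _analysis_region_degree(geometry, rest, truth)
            events = make_event_schedule(
                seed=streams[2], fit_total_s=n_task_vols * tr_s)
            task = simulate_task_run(geometry, truth, region_deg, events,
                                     n_task_vols, tr_s, seed=streams[3])
            crng = np.random.default_rng(streams[4])
            z = (region_deg - truth.degree_center) / truth.degree_scale
            zbar = float(np.mean(z[coupling])) if coupling else 0.0
            craving_pre = float(np.clip(
                crng.normal(truth.craving_pre_mean, truth.craving_pre_sd), 0, 10))
            craving_post = float(np.clip(
                craving_pre + truth.craving_shift + truth.craving_slope * zbar
                + crng.normal(0, truth.craving_noise_sd), 0, 10))
        subjects.append(Subject(
            id=f"sub-{i + 1:03d}", group=group, age_years=float(age),
            duration_months=duration, dosage_g=dosage,
            craving_pre=craving_pre, craving_post=craving_post,
            rest_run=rest, task_run=task, motion_params=rest.motion_params,
        ))
    return Cohort(geometry=geometry, truth=truth, subjects=subjects, seed=seed)
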