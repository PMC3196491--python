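"""File formats: NIfTI volumes, TSV tables, JSON sidecars.

Runs are stored as 4D NIfTI with a JSON sidecar carrying the TR; masks and
region labels as 3D NIfTI; phenotype, events, motion and result tables as
tab-separated UTF-8 text with a header.  Round trips are lossless to float32
precision for volumes and full precision for tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import Geometry
from .synthcohort import Cohort, GroundTruth, RestRun, Subject, TaskRun

__all__ = [
    "write_map",
    "read_map",
    "write_run",
    "read_run",
    "read_phenotype",
    "write_cohort",
    "load_cohort",
]

PHENOTYPE_COLUMNS = [
    "subject", "group", "age", "duration_months", "dosage",
    "craving_pre", "craving_post",
]


def write_map(values: np.ndarray, geometry: Geometry, path) -> None:
    """Write a per-node scalar map as a 3D NIfTI aligned to the geometry."""
    vol = geometry.node_volume(np.asarray(values, dtype=float))
    nib.save(nib.Nifti1Image(vol.astype(np.float32), geometry.affine), str(path))


def read_map(path, geometry: Geometry) -> np.ndarray:
    """Read a 3D NIfTI map back to a per-node vector."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=np.float32)
    if vol.shape != geometry.grid_dims:
        raise ValueError(
            f"{path}: shape {vol.shape} does not match geometry {geometry.grid_dims}"
        )
    return vol.reshape(-1)[geometry.gray_mask]


def write_run(data: np.ndarray, geometry: Geometry, tr_s: float, path) -> None:
    """Write a full-volume voxels x time run as 4D NIfTI + JSON TR sidecar."""
    n_vols = data.shape[1]
    vol4 = np.asarray(data, dtype=np.float32).reshape(*geometry.grid_dims, n_vols)
    img = nib.Nifti1Image(vol4, geometry.affine)
    img.header.set_zooms((*[geometry.spacing_mm] * 3, tr_s))
    nib.save(img, str(path))
    Path(str(path) + ".json").write_text(
        json.dumps({"RepetitionTime": tr_s}), encoding="utf-8"
    )


def read_run(path, geometry: Geometry | None = None) -> tuple[np.ndarray, float]:
    """Read a 4D NIfTI run; returns (voxels x time, TR from the sidecar)."""
    img = nib.load(str(path))
    vol4 = np.asarray(img.dataobj, dtype=np.float32)
    if vol4.ndim != 4:
        raise ValueError(f"{path}: expected a 4D run, got shape {vol4.shape}")
    if geometry is not None and vol4.shape[:3] != geometry.grid_dims:
        raise ValueError(
            f"{path}: grid {vol4.shape[:3]} does not match geometry "
            f"{geometry.grid_dims}"
        )
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        tr = float(json.loads(sidecar.read_text(encoding="utf-8"))["RepetitionTime"])
    else:
        tr = float(img.header.get_zooms()[3])
    return vol4.reshape(-1, vol4.shape[3]).astype(float), tr


def read_phenotype(path) -> pd.DataFrame:
    """Read the phenotype TSV, validating the required columns."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns: {missing}")
    return table


def _write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Serialize a cohort: runs, masks, phenotype, events, ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = cohort.geometry
    for name, arr in (("gray", g.gray_mask), ("wm", g.wm_mask),
                      ("vent", g.vent_mask)):
        vol = arr.reshape(g.grid_dims).astype(np.uint8)
        nib.save(nib.Nifti1Image(vol, g.affine), out / f"mask_{name}.nii")
    nib.save(nib.Nifti1Image(
        g.region_labels.reshape(g.grid_dims).astype(np.int16), g.affine),
        out / "region_labels.nii")
    (out / "geometry.json").write_text(json.dumps({
        "grid_dims": list(g.grid_dims), "spacing_mm": g.spacing_mm,
    }), encoding="utf-8")
    (out / "ground_truth.json").write_text(
        json.dumps(cohort.truth.to_metadata(), indent=2), encoding="utf-8")
    _write_tsv(cohort.phenotype(), out / "phenotype.tsv")
    for s in cohort.subjects:
        write_run(s.rest_run.data, g, s.rest_run.tr_s, out / f"{s.id}_rest.nii")
        _write_tsv(pd.DataFrame(
            s.motion_params, columns=[f"motion_{i}" for i in range(1, 7)]),
            out / f"{s.id}_motion.tsv")
        if s.task_run is not None:
            write_run(s.task_run.data, g, s.task_run.tr_s,
                      out / f"{s.id}_task.nii")
            _write_tsv(s.task_run.events, out / f"{s.id}_events.tsv")


def load_cohort(in_dir) -> Cohort:
    """Reload a serialized cohort into in-memory structures."""
    src = Path(in_dir)
    meta = json.loads((src / "geometry.json").read_text(encoding="utf-8"))
    dims = tuple(meta["grid_dims"])

    def mask(name):
        return np.asarray(
            nib.load(str(src / f"mask_{name}.nii")).dataobj
        ).reshape(-1).astype(bool)

    labels = np.asarray(
        nib.load(str(src / "region_labels.nii")).dataobj
    ).reshape(-1).astype(np.int64)
    coords = np.argwhere(np.ones(dims, dtype=bool))
    geometry = Geometry(
        grid_dims=dims, spacing_mm=float(meta["spacing_mm"]),
        coords_vox=coords, gray_mask=mask("gray"), wm_mask=mask("wm"),
        vent_mask=mask("vent"), region_labels=labels,
    )
    truth_meta = json.loads((src / "ground_truth.json").read_text(encoding="utf-8"))
    truth_meta.pop("craving_model_is_stand_in", None)
    truth = GroundTruth(**truth_meta)
    phenotype = read_phenotype(src / "phenotype.tsv")
    subjects = []
    for _, row in phenotype.iterrows():
        sid = row["subject"]
        rest_data, rest_tr = read_run(src / f"{sid}_rest.nii", geometry)
        motion = pd.read_csv(src / f"{sid}_motion.tsv", sep="\t").to_numpy()
        rest = RestRun(data=rest_data, tr_s=rest_tr, motion_params=motion)
        task = None
        task_path = src / f"{sid}_task.nii"
        if task_path.exists():
            task_data, task_tr = read_run(task_path, geometry)
            events = pd.read_csv(src / f"{sid}_events.tsv", sep="\t")
            task = TaskRun(data=task_data, tr_s=task_tr, events=events)

        def opt(v):
            return None if pd.isna(v) else float(v)

        subjects.append(Subject(
            id=sid, group=row["group"], age_years=float(row["age"]),
            duration_months=opt(row["duration_months"]),
            dosage_g=opt(row["dosage"]),
            craving_pre=opt(row["craving_pre"]),
            craving_post=opt(row["craving_post"]),
            rest_run=rest, task_run=task, motion_params=motion,
        ))
    return Cohort(geometry=geometry, truth=truth, subjects=subjects,
                  seed=truth.seed)
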