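"""Weighted region-based networks built from voxel-level group differences.

Regions of interest are 12-mm-diameter spheres centred on the
maximally-abnormal voxel of each anatomical region that contains a surviving
degree-contrast cluster (minimum extent 3 voxels); white-matter and
ventricle voxels never enter an ROI.  ROI mean time courses are correlated
pairwise into a fully connected weighted network (R regions -> R(R-1)/2
unique edges), compared edgewise between groups, and related to dependence
duration by age-controlled partial correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Geometry
from .inference import NodalContrast, partial_corr, fdr_bh, _vectorized_pooled_t

__all__ = [
    "ROI",
    "select_rois",
    "sphere_members",
    "roi_timeseries",
    "weighted_network",
    "edge_vector",
    "edgewise_group_test",
    "edge_duration_correlation",
]


@dataclass(frozen=True)
class ROI:
    label: str
    region: int
    center_node: int
    center_mm: tuple[float, float, float]
    members: np.ndarray  # node ids, including the centre


def sphere_members(
    geometry: Geometry,
    center_node: int,
    sphere_diameter_mm: float = 12.0,
) -> np.ndarray:
    """Gray-matter nodes within (inclusive) radius of the centre node's mm position.

    Gray nodes only, so white matter and ventricles are excluded by
    construction.
    """
    coords = geometry.node_coords_mm
    d = np.linalg.norm(coords - coords[center_node], axis=1)
    return np.nonzero(d <= sphere_diameter_mm / 2.0 + 1e-9)[0]


def select_rois(
    contrast: NodalContrast,
    geometry: Geometry,
    min_cluster: int = 3,
    sphere_diameter_mm: float = 12.0,
) -> list[ROI]:
    """Turn surviving degree-contrast clusters into spherical ROIs.

    Clusters below ``min_cluster`` voxels were already dropped by the
    contrast (isolated suprathreshold voxels never seed an ROI).  For every
    anatomical region containing at least one surviving voxel, the centre is
    the voxel with the largest |t| (ties resolved to the lowest node index),
    and the ROI is the sphere of gray voxels around it.
    """
    surviving = np.nonzero(contrast.surviving)[0]
    if surviving.size == 0:
        warnings.warn("no surviving cluster anywhere; returning no ROIs",
                      stacklevel=2)
        return []
    regions = geometry.node_regions
    rois: list[ROI] = []
    for k, region in enumerate(np.unique(regions[surviving])):
        nodes = surviving[regions[surviving] == region]
        center = int(nodes[np.argmax(np.abs(contrast.t[nodes]))])
        members = sphere_members(geometry, center, sphere_diameter_mm)
        coord = tuple(float(v) for v in geometry.node_coords_mm[center])
        rois.append(ROI(
            label=f"roi{k:02d}_region{int(region)}",
            region=int(region),
            center_node=center,
            center_mm=coord,
            members=members,
        ))
    return rois


def roi_timeseries(series: np.ndarray, rois: list[ROI]) -> np.ndarray:
    """R x time matrix of mean time courses over each ROI's member voxels."""
    if not rois:
        raise ValueError("no ROIs supplied")
    x = np.asarray(series, dtype=float)
    return np.stack([x[roi.members].mean(axis=0) for roi in rois])


def weighted_network(roi_ts: np.ndarray) -> np.ndarray:
    """Full symmetric Pearson correlation matrix over ROI time courses.

    The R x R matrix carries R(R-1)/2 unique edges; correlation values are
    kept as edge weights.
    """
    x = np.asarray(roi_ts, dtype=float)
    sd = x.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance ROI time series: ROIs {bad.tolist()}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def edge_vector(weights: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle flattening of an R x R weight matrix."""
    w = np.asarray(weights, dtype=float)
    iu = np.triu_indices(w.shape[0], k=1)
    return w[iu]


def _edge_index(n_edges: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if r * (r - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} is not a triangular number of edges")
    return np.triu_indices(r, k=1)


def edgewise_group_test(
    weights_a: np.ndarray,
    weights_b: np.ndarray,
    q: float = 0.05,
    fisher: bool = True,
    group_names: tuple[str, str] = ("CHU", "NDU"),
) -> pd.DataFrame:
    """Per-edge group comparison of connection weights.

    ``weights_a``/``weights_b`` are subjects x edges (upper-triangle order).
    Weights are Fisher z-transformed by default (variance-stabilizing; set
    ``fisher=False`` to test raw correlations), then compared with the
    pooled two-sample t and BH FDR at ``q``.  Direction labels give the
    red/blue split (first group greater vs smaller).
    """
    a = np.asarray(weights_a, dtype=float)
    b = np.asarray(weights_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("edge count mismatch between groups")
    if fisher:
        for name, w in zip(group_names, (a, b)):
            at_one = np.nonzero(np.any(np.abs(w) >= 1.0, axis=0))[0]
            if at_one.size:
                raise ValueError(
                    f"|r| = 1 in group {name} at edges {at_one.tolist()}; "
                    "Fisher z is infinite"
                )
        a = np.arctanh(a)
        b = np.arctanh(b)
    t, p = _vectorized_pooled_t(a, b)
    rejected = fdr_bh(p, q=q)
    gi, gj = _edge_index(a.shape[1])
    direction = np.where(
        a.mean(axis=0) > b.mean(axis=0),
        f"{group_names[0]}>{group_names[1]}",
        f"{group_names[0]}<{group_names[1]}",
    )
    direction[t == 0] = "none"
    return pd.DataFrame({
        "roi_i": gi, "roi_j": gj, "t": t, "p": p,
        "rejected": rejected, "direction": direction,
    })


def edge_duration_correlation(
    weights: np.ndarray,
    duration: np.ndarray,
    age: np.ndarray,
) -> pd.DataFrame:
    """Age-controlled partial correlation of each edge weight with duration.

    Applied to the patient group only; ``weights`` is subjects x edges.
    """
    w = np.asarray(weights, dtype=float)
    duration = np.asarray(duration, dtype=float)
    age = np.asarray(age, dtype=float)
    if w.shape[0] <= 3:
        raise ValueError("need more than 3 subjects")
    rs, ps = [], []
    for e in range(w.shape[1]):
        r, p = partial_corr(w[:, e], duration, covariates=age)
        rs.append(r)
        ps.append(p)
    gi, gj = _edge_index(w.shape[1])
    return pd.DataFrame({
        "roi_i": gi, "roi_j": gj,
        "partial_r_duration": rs, "p": ps,
    })
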