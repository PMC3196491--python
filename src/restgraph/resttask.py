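"""Rest-task interaction: resting degree vs cue-evoked activation and craving.

For each region of interest, per-subject resting nodal degree (ROI mean, at
the sweep's most significant threshold) is correlated across the patient
group with the same region's cue-reactivity contrast amplitude and with the
cue-induced craving change (post minus pre).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .roinet import ROI

__all__ = [
    "degree_activation_corr",
    "degree_craving_corr",
    "region_mean_degree",
    "interaction_table",
]


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must be the same length (same subjects)")
    if x.size < 4:
        raise ValueError("need at least 4 subjects")
    if x.std() == 0 or y.std() == 0:
        which = "first" if x.std() == 0 else "second"
        raise ValueError(f"zero variance in the {which} vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def degree_activation_corr(degree_per_subject, contrast_per_subject):
    """Pearson r (and two-tailed p) of resting degree vs task contrast."""
    return _pearson(degree_per_subject, contrast_per_subject)


def degree_craving_corr(degree_per_subject, craving_change):
    """Pearson r (and two-tailed p) of resting degree vs craving change."""
    return _pearson(degree_per_subject, craving_change)


def region_mean_degree(degree_map_per_subject: np.ndarray, roi: ROI,
                       statistic: str = "mean") -> np.ndarray:
    """Per-subject ROI degree: mean over members, or the centre (peak) voxel.

    ``degree_map_per_subject`` is subjects x nodes.
    """
    d = np.atleast_2d(np.asarray(degree_map_per_subject, dtype=float))
    members = np.asarray(roi.members, dtype=int)
    if members.size == 0:
        raise ValueError("ROI has no member voxels")
    if members.max() >= d.shape[1]:
        raise ValueError("ROI members exceed the degree map's node count")
    if statistic == "mean":
        return d[:, members].mean(axis=1)
    if statistic == "peak":
        return d[:, roi.center_node]
    raise ValueError(f"unknown statistic {statistic!r}")


def interaction_table(
    rois: list[ROI],
    degree_maps: np.ndarray,
    contrast_maps: np.ndarray,
    craving_change: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-ROI degree-activation (and optionally degree-craving) correlations.

    All arrays are over the same patient subjects in the same order;
    ``degree_maps`` and ``contrast_maps`` are subjects x nodes.
    """
    rows = []
    for roi in rois:
        deg = region_mean_degree(degree_maps, roi)
        act = region_mean_degree(contrast_maps, roi)  # same ROI averaging
        r_a, p_a = degree_activation_corr(deg, act)
        row = {
            "roi": roi.label, "region": roi.region, "n": deg.size,
            "r_activation": r_a, "p_activation": p_a,
        }
        if craving_change is not None:
            r_c, p_c = degree_craving_corr(deg, craving_change)
            row.update({"r_craving": r_c, "p_craving": p_c})
        rows.append(row)
    return pd.DataFrame(rows)
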