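"""Voxel-level correlation networks and threshold sweeps.

A Pearson correlation matrix over all node pairs is binarized at each
threshold T of a sweep grid (default 0.36 to 0.60 in 0.01 increments).  An
edge exists when r >= T; negative correlations never produce edges, keeping
the sign of correlations interpretable (the pipeline does not regress the
global signal for the same reason).  The lower bound of the sweep is chosen
so that every subject's graph is fully connected.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "correlation_matrix",
    "binarize",
    "largest_component_fraction",
    "find_lower_bound_threshold",
    "default_threshold_grid",
]


def default_threshold_grid(t_min: float = 0.36, t_max: float = 0.60,
                           t_step: float = 0.01) -> np.ndarray:
    """The sweep grid; defaults give the 25 values 0.36, 0.37, ..., 0.60."""
    n = int(round((t_max - t_min) / t_step))
    return np.round(t_min + t_step * np.arange(n + 1), 10)


def correlation_matrix(series: np.ndarray) -> np.ndarray:
    """Pearson correlation between every pair of node time series.

    The result is exactly symmetric with unit diagonal and entries clipped
    to [-1, 1].  Nodes with zero temporal variance are an error.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be node x time")
    sd = x.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance node time series: nodes {bad.tolist()}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def binarize(corr: np.ndarray, threshold: float,
             absolute: bool = False) -> np.ndarray:
    """Adjacency at threshold T: edge iff r_ij >= T and i != j.

    Only positive correlations at or above T become edges by default;
    ``absolute=True`` thresholds |r| instead.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    r = np.asarray(corr, dtype=float)
    if absolute:
        r = np.abs(r)
    adj = (r >= threshold).astype(np.int64)
    np.fill_diagonal(adj, 0)
    return adj


def largest_component_fraction(adj: np.ndarray) -> float:
    """Size of the largest connected component divided by the node count."""
    a = np.asarray(adj)
    n = a.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    n_comp, labels = connected_components(csr_matrix(a), directed=False)
    if n_comp == 1:
        return 1.0
    return float(np.bincount(labels).max()) / n


def find_lower_bound_threshold(
    corrs: list[np.ndarray],
    t_grid: np.ndarray,
) -> float:
    """Largest grid threshold at which every subject's graph is fully connected.

    Mirrors the choice of the sweep lower bound: the network must contain all
    nodes in one component for every subject.  If no grid value qualifies,
    the grid minimum is returned with a warning.
    """
    grid = np.asarray(t_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("threshold grid must be strictly ascending")
    if not corrs:
        raise ValueError("no correlation matrices supplied")
    # connectivity is monotone in T, so scan from the top down
    for t in grid[::-1]:
        if all(largest_component_fraction(binarize(c, t)) == 1.0 for c in corrs):
            return float(t)
    warnings.warn(
        "no grid threshold yields fully connected graphs for every subject; "
        "returning the grid minimum",
        stacklevel=2,
    )
    return float(grid[0])
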