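"""Topological statistics of binary brain graphs.

Implements the Watts-Strogatz clustering coefficient, characteristic path
length, global efficiency, nodal degree, and small-worldness relative to an
ensemble of degree-preserving (double-edge-swap) random null graphs.  All
functions operate on dense symmetric 0/1 adjacency matrices with zero
diagonal; shortest paths are unweighted edge counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "MetricRecord",
    "SmallWorldResult",
    "clustering",
    "path_length",
    "global_efficiency",
    "degree",
    "degree_preserving_rewire",
    "small_world",
]


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have zero diagonal (no self-loops)")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    return a.astype(np.int64, copy=False)


def degree(adj: np.ndarray) -> np.ndarray:
    """Per-node degree: number of suprathreshold connections (row sums)."""
    return _check_adjacency(adj).sum(axis=1)


def clustering(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Watts-Strogatz clustering coefficient.

    C_i is the fraction of pairs of neighbours of node i that are themselves
    connected: C_i = t_i / (k_i choose 2), where t_i counts triangles through
    i.  Nodes with degree < 2 are assigned C_i = 0.  Returns (C_i, mean C)
    with the mean taken over all nodes.
    """
    a = _check_adjacency(adj)
    k = a.sum(axis=1)
    # diag(A^3)_i = 2 * triangles through i, computed without forming A^3
    tri2 = ((a @ a) * a).sum(axis=1)  # = diag(A^3)
    denom = k * (k - 1)  # 2 * (k choose 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(k >= 2, tri2 / np.maximum(denom, 1), 0.0)
    return ci, float(ci.mean())


def _distance_matrix(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def path_length(adj: np.ndarray) -> float:
    """Characteristic path length: mean shortest-path edge count over pairs.

    Raises on a disconnected graph; callers are expected to gate on full
    connectedness (see voxelnet.largest_component_fraction) first.
    """
    a = _check_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("path length undefined for graphs with < 2 nodes")
    d = _distance_matrix(a)
    iu = np.triu_indices(n, k=1)
    dv = d[iu]
    if np.isinf(dv).any():
        raise ValueError(
            "graph is disconnected; characteristic path length is undefined "
            "(gate on largest_component_fraction == 1 before calling)"
        )
    return float(dv.mean())


def global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length over node pairs.

    Unreachable pairs contribute 0, so disconnection is allowed.
    """
    a = _check_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = _distance_matrix(a)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    inv[np.isinf(d[iu])] = 0.0
    return float(inv.mean())


def degree_preserving_rewire(
    adj: np.ndarray,
    swaps_per_edge: float = 10,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Randomize a graph by double-edge swaps, preserving every degree.

    Attempts ``swaps_per_edge * |E|`` swaps; a proposed swap is rejected when
    it would create a self-loop or a multi-edge, so the output is always a
    simple graph with exactly the input degree sequence.  Graphs with fewer
    than two edges are returned unchanged with a warning.
    """
    a = _check_adjacency(adj)
    if rng is None:
        rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(a, k=1))
    m = len(iu)
    if m < 2:
        warnings.warn("graph has < 2 edges; no rewiring possible", stacklevel=2)
        return a.copy()
    edges = list(zip(iu.tolist(), ju.tolist()))
    edge_set = set(edges)
    n_attempts = int(round(swaps_per_edge * m))
    pick = rng.integers(0, m, size=(n_attempts, 2))
    flip = rng.integers(0, 2, size=n_attempts)
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip[t]:
            x, y = y, x
        # rewire (u,v),(x,y) -> (u,x),(v,y)
        if u == x or v == y:
            continue
        new1 = (min(u, x), max(u, x))
        new2 = (min(v, y), max(v, y))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
    out = np.zeros_like(a)
    if edges:
        ei, ej = np.array(edges).T
        out[ei, ej] = 1
        out[ej, ei] = 1
    return out


def _largest_component_mask(a: np.ndarray) -> np.ndarray:
    n_comp, labels = connected_components(csr_matrix(a), directed=False)
    if n_comp == 1:
        return np.ones(a.shape[0], dtype=bool)
    sizes = np.bincount(labels)
    return labels == np.argmax(sizes)


@dataclass
class SmallWorldResult:
    """C, L and their degree-matched null means, plus the derived ratios."""

    C: float
    L: float
    C_rand: float
    L_rand: float
    gamma: float
    lam: float
    sigma: float
    n_disconnected_nulls: int = 0


@dataclass
class MetricRecord:
    """Per-subject, per-threshold bundle of network statistics."""

    subject: str
    threshold: float
    C: float
    L: float
    E_glob: float
    C_rand: float
    L_rand: float
    gamma: float
    lam: float
    sigma: float
    degree: np.ndarray = field(repr=False, default=None)


def small_world(
    adj: np.ndarray,
    n_null: int = 20,
    swaps_per_edge: float = 10,
    seed: int = 0,
) -> SmallWorldResult:
    """Small-world ratios against a degree-preserving null ensemble.

    gamma = C / C_rand, lambda = L / L_rand, sigma = gamma / lambda, where
    C_rand and L_rand are means over ``n_null`` independently rewired graphs.
    A null that happens to disconnect has its L computed on its largest
    component; the count of such nulls is recorded.
    """
    a = _check_adjacency(adj)
    _, c = clustering(a)
    ell = path_length(a)  # raises if disconnected
    ss = np.random.SeedSequence(seed)
    c_nulls, l_nulls = [], []
    n_disc = 0
    for child in ss.spawn(n_null):
        rng = np.random.default_rng(child)
        null = degree_preserving_rewire(a, swaps_per_edge=swaps_per_edge, rng=rng)
        _, cn = clustering(null)
        mask = _largest_component_mask(null)
        if not mask.all():
            n_disc += 1
            null = null[np.ix_(mask, mask)]
        l_nulls.append(path_length(null))
        c_nulls.append(cn)
    if n_disc:
        logger.info("%d of %d rewired nulls were disconnected; L taken on "
                    "their largest components", n_disc, n_null)
    c_rand = float(np.mean(c_nulls))
    l_rand = float(np.mean(l_nulls))
    gamma = c / c_rand if c_rand > 0 else np.nan
    lam = ell / l_rand if l_rand > 0 else np.nan
    sigma = gamma / lam if lam and np.isfinite(lam) else np.nan
    return SmallWorldResult(
        C=c, L=ell, C_rand=c_rand, L_rand=l_rand,
        gamma=gamma, lam=lam, sigma=sigma, n_disconnected_nulls=n_disc,
    )
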