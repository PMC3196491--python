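"""Statistical comparisons for the network analysis.

Group differences use the pooled-variance (Student) two-sample two-tailed
t-test; multiple testing is controlled with Benjamini-Hochberg FDR.  Partial
correlations residualize both variables on the covariates (plus intercept)
and correlate the residuals.  Voxel-wise degree contrasts are reported as
clusters of face-adjacent suprathreshold voxels, dropping clusters below a
minimum extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .geometry import Geometry

__all__ = [
    "StatResult",
    "two_sample_t",
    "fdr_bh",
    "partial_corr",
    "paired_t",
    "nodal_degree_contrast",
    "sweep_contrast",
    "NodalContrast",
    "Cluster",
    "SweepContrast",
]


@dataclass
class StatResult:
    t: float
    df: float
    p: float
    direction: str  # "A>B", "A<B" or "none"
    degenerate: bool = False


def _direction(mean_a: float, mean_b: float) -> str:
    if mean_a > mean_b:
        return "A>B"
    if mean_a < mean_b:
        return "A<B"
    return "none"


def two_sample_t(x, y, welch: bool = False) -> StatResult:
    """Two-sample two-tailed t-test.

    Pooled-variance (Student) by default, df = n_a + n_b - 2; ``welch=True``
    switches to the Welch test with Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        equal = x.mean() == y.mean()
        return StatResult(t=0.0 if equal else np.inf, df=df,
                          p=1.0 if equal else 0.0,
                          direction=_direction(x.mean(), y.mean()),
                          degenerate=True)
    res = stats.ttest_ind(x, y, equal_var=not welch)
    if welch:
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (vx + vy) ** 2 / (vx ** 2 / (x.size - 1)
                               + vy ** 2 / (y.size - 1))
    return StatResult(t=float(res.statistic), df=float(df),
                      p=float(res.pvalue),
                      direction=_direction(x.mean(), y.mean()))


def paired_t(pre, post) -> StatResult:
    """One-sample t on post-minus-pre differences (df = n - 1)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    if pre.size < 2:
        raise ValueError("need at least 2 pairs")
    d = post - pre
    if d.std(ddof=1) == 0:
        equal = d.mean() == 0
        return StatResult(t=0.0 if equal else np.inf, df=pre.size - 1,
                          p=1.0 if equal else 0.0,
                          direction=_direction(post.mean(), pre.mean()),
                          degenerate=True)
    res = stats.ttest_rel(post, pre)
    return StatResult(t=float(res.statistic), df=pre.size - 1,
                      p=float(res.pvalue),
                      direction=_direction(post.mean(), pre.mean()))


def fdr_bh(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def partial_corr(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after removing covariates from both.

    Both variables are residualized on the covariates plus an intercept; the
    p-value comes from t = r * sqrt((n - 2 - k) / (1 - r^2)) with k the
    number of covariates.  With no covariates this reduces to the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    k = c.shape[1]
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    design = np.column_stack([np.ones(n), c])
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ bx
    ry = y - design @ by
    sx, sy = rx.std(), ry.std()
    tol_x = 1e-10 * (np.abs(x).max() + 1.0)
    tol_y = 1e-10 * (np.abs(y).max() + 1.0)
    if sx <= tol_x or sy <= tol_y:
        which = "x" if sx <= tol_x else "y"
        raise ValueError(f"zero residual variance in {which}")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def _vectorized_pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise pooled-variance t with degenerate columns mapped to t=0,p=1."""
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        degenerate = sp2 == 0
        t = np.where(degenerate,
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.nan_to_num(t)), df))
    p = np.where(degenerate & (diff == 0), 1.0, p)
    return t, p


@dataclass
class Cluster:
    nodes: np.ndarray            # node indices in the cluster
    size: int
    peak_node: int               # node with max |t|
    peak_coord_mm: tuple[float, float, float]
    region: int                  # anatomical region of the peak
    mean_degree_a: float
    mean_degree_b: float
    peak_t: float


@dataclass
class NodalContrast:
    t: np.ndarray
    p: np.ndarray
    rejected: np.ndarray         # FDR-surviving nodes before the extent rule
    surviving: np.ndarray        # nodes inside clusters of >= min_cluster voxels
    clusters: list[Cluster] = field(default_factory=list)


def _label_clusters(mask_nodes: np.ndarray, geometry: Geometry) -> list[np.ndarray]:
    """Group suprathreshold nodes into 6-connected (face-adjacent) clusters."""
    flat = np.zeros(geometry.n_total, dtype=bool)
    flat[np.nonzero(geometry.gray_mask)[0][mask_nodes]] = True
    vol = flat.reshape(geometry.grid_dims)
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    labels, n = ndimage.label(vol, structure=structure)
    labels_flat = labels.reshape(-1)[geometry.gray_mask]
    return [np.nonzero(labels_flat == i)[0] for i in range(1, n + 1)]


def nodal_degree_contrast(
    degrees_a: np.ndarray,
    degrees_b: np.ndarray,
    geometry: Geometry,
    q: float = 0.05,
    min_cluster: int = 3,
    correction: str = "fdr_bh",
) -> NodalContrast:
    """Per-node degree contrast between groups, FDR + cluster-extent rule.

    ``degrees_a``/``degrees_b`` are subjects x nodes.  Each node gets a
    pooled two-sample t; nodes surviving BH FDR at level ``q`` (or
    Bonferroni with ``correction="bonferroni"``) are grouped into
    face-adjacent clusters and clusters smaller than ``min_cluster`` voxels
    are dropped from the report.
    """
    a = np.asarray(degrees_a, dtype=float)
    b = np.asarray(degrees_b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"node count mismatch: group A has {a.shape[1]}, group B {b.shape[1]}"
        )
    if a.shape[1] != geometry.n_nodes:
        raise ValueError("degree matrices do not match the geometry's node count")
    t, p = _vectorized_pooled_t(a, b)
    if correction == "fdr_bh":
        rejected = fdr_bh(p, q=q)
    elif correction == "bonferroni":
        rejected = p <= q / p.size
    else:
        raise ValueError(f"unknown correction {correction!r}")
    clusters: list[Cluster] = []
    surviving = np.zeros_like(rejected)
    if rejected.any():
        coords = geometry.node_coords_mm
        regions = geometry.node_regions
        for nodes in _label_clusters(rejected, geometry):
            if nodes.size < min_cluster:
                continue
            surviving[nodes] = True
            peak = nodes[np.argmax(np.abs(t[nodes]))]
            clusters.append(Cluster(
                nodes=nodes,
                size=int(nodes.size),
                peak_node=int(peak),
                peak_coord_mm=tuple(coords[peak]),
                region=int(regions[peak]),
                mean_degree_a=float(a[:, nodes].mean()),
                mean_degree_b=float(b[:, nodes].mean()),
                peak_t=float(t[peak]),
            ))
    return NodalContrast(t=t, p=p, rejected=rejected, surviving=surviving,
                         clusters=clusters)


@dataclass
class SweepContrast:
    table: pd.DataFrame                 # threshold, t, p, rejected
    best_threshold: float
    significant_range: tuple[float, float] | None


def sweep_contrast(
    metrics_a: np.ndarray,
    metrics_b: np.ndarray,
    t_grid: np.ndarray,
    q: float = 0.05,
) -> SweepContrast:
    """Group contrast of a scalar network metric across the threshold sweep.

    ``metrics_a``/``metrics_b`` are subjects x thresholds.  Applies the
    pooled t per threshold, FDR across thresholds, and reports the
    contiguous significant range containing the most significant threshold
    (minimum p, ties broken toward the larger threshold).
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    grid = np.asarray(t_grid, dtype=float)
    if a.shape[1] != grid.size or b.shape[1] != grid.size:
        raise ValueError("metric matrices must have one column per threshold")
    t, p = _vectorized_pooled_t(a, b)
    rejected = fdr_bh(p, q=q)
    # argmin p, ties toward larger T
    best_idx = grid.size - 1 - int(np.argmin(p[::-1]))
    sig_range = None
    if rejected[best_idx]:
        lo = best_idx
        while lo > 0 and rejected[lo - 1]:
            lo -= 1
        hi = best_idx
        while hi < grid.size - 1 and rejected[hi + 1]:
            hi += 1
        sig_range = (float(grid[lo]), float(grid[hi]))
    table = pd.DataFrame({
        "threshold": grid, "t": t, "p": p, "rejected": rejected,
    })
    return SweepContrast(table=table, best_threshold=float(grid[best_idx]),
                         significant_range=sig_range)
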