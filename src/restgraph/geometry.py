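"""Voxel lattice geometry: coordinates, tissue masks, anatomical parcels.

The analysis operates on a regular 3D grid of voxels (default 3 mm spacing,
mimicking data down-sampled to a coarser isotropic lattice).  Voxels are
partitioned into mutually exclusive gray-matter, deep-white-matter and
ventricle compartments; gray voxels additionally carry an anatomical region
label produced by a seeded Voronoi parcellation, standing in for an atlas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Geometry", "make_geometry"]


@dataclass(frozen=True)
class Geometry:
    grid_dims: tuple[int, int, int]
    spacing_mm: float
    coords_vox: np.ndarray      # (n_total, 3) integer lattice coordinates
    gray_mask: np.ndarray       # (n_total,) bool, mutually exclusive masks
    wm_mask: np.ndarray
    vent_mask: np.ndarray
    region_labels: np.ndarray   # (n_total,) int, -1 outside gray matter

    @property
    def n_total(self) -> int:
        return self.coords_vox.shape[0]

    @property
    def n_nodes(self) -> int:
        """Number of gray-matter voxels (network nodes)."""
        return int(self.gray_mask.sum())

    @property
    def coords_mm(self) -> np.ndarray:
        return self.coords_vox * self.spacing_mm

    @property
    def node_coords_mm(self) -> np.ndarray:
        """mm coordinates of gray voxels, in node order."""
        return self.coords_mm[self.gray_mask]

    @property
    def node_regions(self) -> np.ndarray:
        """Anatomical region label per node."""
        return self.region_labels[self.gray_mask]

    @property
    def n_regions(self) -> int:
        return int(self.node_regions.max()) + 1

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.spacing_mm
        return a

    def node_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-node values back into a full 3D volume."""
        flat = np.full(self.n_total, fill, dtype=float)
        flat[self.gray_mask] = values
        return flat.reshape(self.grid_dims)


def make_geometry(
    grid_dims: tuple[int, int, int],
    n_regions: int,
    spacing_mm: float = 3.0,
    seed: int = 0,
    wm_frac: float = 0.15,
    vent_frac: float = 0.05,
) -> Geometry:
    """Build a deterministic synthetic geometry.

    Ventricle voxels are the ``vent_frac`` lattice points nearest the grid
    centre and white matter the next ``wm_frac`` shell, emulating deep
    midline structures; everything else is gray matter.  Gray voxels are
    parcellated into ``n_regions`` contiguous Voronoi cells around seeded
    gray voxels (ties broken toward the lower seed index).
    """
    dims = tuple(int(d) for d in grid_dims)
    if len(dims) != 3 or any(d < 2 for d in dims):
        raise ValueError("grid_dims must be three integers, each >= 2")
    coords = np.argwhere(np.ones(dims, dtype=bool))  # C-order lattice points
    n_total = coords.shape[0]
    center = (np.array(dims) - 1) / 2.0
    dist = np.linalg.norm(coords - center, axis=1)
    order = np.lexsort((np.arange(n_total), dist))  # stable: distance, then index
    n_vent = max(int(round(vent_frac * n_total)), 1) if vent_frac > 0 else 0
    n_wm = max(int(round(wm_frac * n_total)), 1) if wm_frac > 0 else 0
    vent_mask = np.zeros(n_total, dtype=bool)
    wm_mask = np.zeros(n_total, dtype=bool)
    vent_mask[order[:n_vent]] = True
    wm_mask[order[n_vent:n_vent + n_wm]] = True
    gray_mask = ~(vent_mask | wm_mask)
    n_gray = int(gray_mask.sum())
    if n_regions > n_gray:
        raise ValueError(
            f"n_regions={n_regions} exceeds the {n_gray} gray-matter voxels"
        )
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    gray_idx = np.nonzero(gray_mask)[0]
    # farthest-point seeding gives roughly even parcels; the first seed is
    # random, each next seed maximizes distance to those already chosen
    first = rng.choice(gray_idx)
    seeds = [int(first)]
    gray_coords = coords[gray_idx]
    dmin = np.linalg.norm(gray_coords - coords[first], axis=1)
    for _ in range(n_regions - 1):
        nxt = gray_idx[int(np.argmax(dmin))]
        seeds.append(int(nxt))
        dmin = np.minimum(dmin, np.linalg.norm(gray_coords - coords[nxt], axis=1))
    seeds = np.array(seeds)
    # nearest-seed assignment; argmin takes the lowest seed index on ties
    d2 = ((coords[gray_idx][:, None, :] - coords[seeds][None, :, :]) ** 2).sum(axis=2)
    labels = np.full(n_total, -1, dtype=np.int64)
    labels[gray_idx] = np.argmin(d2, axis=1)
    return Geometry(
        grid_dims=dims,
        spacing_mm=float(spacing_mm),
        coords_vox=coords,
        gray_mask=gray_mask,
        wm_mask=wm_mask,
        vent_mask=vent_mask,
        region_labels=labels,
    )
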