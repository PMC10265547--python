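"""Streamline-density maps, binary masks and group heat maps.

Density is the streamline-visit count: each streamline contributes exactly 1
to every distinct voxel it traverses, with traversal decided by the same
arc-length resampling contract as bundle selection. Summed binary masks of
replicate bundles form voxel-wise heat maps of inter-replicate agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dissect import default_step_mm, resample_polyline
from .io import ReferenceGrid, Tractogram, world_to_voxel
from .voi import VOIMask

__all__ = ["DensityMap", "HeatMap", "density_map", "binary_mask", "heat_map"]


@dataclass
class DensityMap:
    counts: np.ndarray
    grid: ReferenceGrid
    n_streamlines: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if tuple(self.counts.shape) != self.grid.shape:
            raise ValueError("counts shape does not match grid")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("density counts must be integers")
        if self.counts.min() < 0 or (self.counts.size and self.counts.max() > self.n_streamlines):
            raise ValueError("voxel counts must lie in [0, n_streamlines]")


@dataclass
class HeatMap:
    sums: np.ndarray
    grid: ReferenceGrid
    n_inputs: int


def density_map(tractogram: Tractogram, grid: ReferenceGrid | None = None, step_mm: float | None = None) -> DensityMap:
    """Per-voxel count of streamlines traversing each voxel."""
    if grid is None:
        grid = tractogram.grid
    if grid is None:
        raise ValueError("a reference grid is required")
    if step_mm is None:
        step_mm = default_step_mm(grid)
    counts = np.zeros(grid.shape, dtype=np.int32)
    for s in tractogram:
        samples = resample_polyline(s, step_mm)
        idx, in_grid = world_to_voxel(samples, grid)
        idx = idx[in_grid]
        if len(idx) == 0:
            continue
        visited = np.unique(idx, axis=0)
        counts[visited[:, 0], visited[:, 1], visited[:, 2]] += 1
    return DensityMap(counts, grid, n_streamlines=len(tractogram))


def binary_mask(dmap: DensityMap, min_count: int = 1) -> VOIMask:
    """Binarize a density map at a minimum visit count."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return VOIMask(dmap.counts >= min_count, dmap.grid)


def heat_map(masks: list[VOIMask]) -> HeatMap:
    """Voxel-wise sum of binary masks sharing one grid."""
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise ValueError("heat_map requires masks on a shared grid")
    sums = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        sums += m.data.astype(np.int32)
    return HeatMap(sums, grid, n_inputs=len(masks))
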