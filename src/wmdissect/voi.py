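"""Materialize VOI specifications into binary masks on a reference grid.

All masks share the parcellation's grid so that bundle selection can combine
them voxel-wise. Conventions fixed for determinism: boxes are closed in world
space, dilation is 6-connected, and the midsagittal slab is half-open toward
higher world x (tie-break toward the lower index on even grids).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ReferenceGrid, voxel_to_world
from .registry import BundleDefinition, VOISpec

__all__ = [
    "ParcellationVolume",
    "VOIMask",
    "labels_to_mask",
    "box_mask",
    "midsagittal_mask",
    "dilate_mask",
    "materialize",
    "MaterializationError",
]

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class MaterializationError(ValueError):
    """A VOI spec cannot be turned into a mask on this parcellation."""


@dataclass
class ParcellationVolume:
    """Integer label volume with a name -> label-id table."""

    data: np.ndarray
    grid: ReferenceGrid
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("parcellation data must be 3-D")
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError("parcellation shape does not match grid")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("parcellation must hold integer labels")

    def resolve(self, name: str) -> int:
        try:
            return self.labels[name]
        except KeyError:
            raise MaterializationError(f"label name {name!r} not in parcellation table") from None


@dataclass
class VOIMask:
    data: np.ndarray
    grid: ReferenceGrid
    provenance: VOISpec | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def volume_voxels(self) -> int:
        return int(self.data.sum())


def labels_to_mask(parcellation: ParcellationVolume, label_ids) -> VOIMask:
    """Mask of all voxels whose label is in ``label_ids``.

    Absent label ids contribute nothing and trigger a warning, not an error.
    """
    ids = [int(i) for i in label_ids]
    if not ids:
        raise ValueError("label_ids must be non-empty")
    present = set(np.unique(parcellation.data).tolist())
    missing = [i for i in ids if i not in present]
    if missing:
        warnings.warn(f"label ids {missing} absent from parcellation", stacklevel=2)
    mask = np.isin(parcellation.data, ids)
    spec = VOISpec(kind="labels", label_ids=tuple(ids))
    return VOIMask(mask, parcellation.grid, provenance=spec)


def _voxel_center_coords(grid: ReferenceGrid) -> np.ndarray:
    """World coordinates of all voxel centers, shape (*grid.shape, 3)."""
    idx = np.indices(grid.shape).reshape(3, -1).T
    return voxel_to_world(idx, grid).reshape(*grid.shape, 3)


def box_mask(grid: ReferenceGrid, corners_mm) -> VOIMask:
    """Voxels whose centers fall inside the closed world-space box."""
    c = np.asarray(corners_mm, dtype=float)
    if c.shape != (2, 3):
        raise ValueError("corners_mm must be two 3-D world points")
    lo, hi = np.minimum(c[0], c[1]), np.maximum(c[0], c[1])
    if np.any(hi - lo <= 0):
        raise ValueError(f"degenerate box with corners {corners_mm}")
    centers = _voxel_center_coords(grid)
    mask = np.all((centers >= lo) & (centers <= hi), axis=-1)
    spec = VOISpec(kind="box", corners_mm=tuple(tuple(x) for x in c))
    return VOIMask(mask, grid, provenance=spec)


def midsagittal_mask(grid: ReferenceGrid, thickness_mm: float) -> VOIMask:
    """Slab around the world-x of the grid center.

    Half-open toward +x: a voxel center at exactly +thickness/2 from the
    mid-plane is excluded, one at -thickness/2 included, which picks the
    lower-index slab on even grids when thickness equals the voxel size.
    """
    if thickness_mm <= 0:
        raise ValueError("thickness_mm must be > 0")
    center_idx = (np.asarray(grid.shape, dtype=float) - 1.0) / 2.0
    x_mid = voxel_to_world(center_idx, grid)[0, 0]
    x = _voxel_center_coords(grid)[..., 0]
    half = thickness_mm / 2.0
    mask = (x - x_mid >= -half) & (x - x_mid < half)
    return VOIMask(mask, grid, provenance=VOISpec(kind="midsagittal", thickness_mm=thickness_mm))


def dilate_mask(mask: VOIMask, iterations: int) -> VOIMask:
    """6-connected binary dilation applied ``iterations`` times."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or not mask.data.any():
        return VOIMask(mask.data.copy(), mask.grid, provenance=mask.provenance)
    data = ndimage.binary_dilation(mask.data, structure=_STRUCT_6, iterations=iterations)
    return VOIMask(data, mask.grid, provenance=mask.provenance)


def materialize_spec(spec: VOISpec, parcellation: ParcellationVolume) -> VOIMask:
    if spec.kind == "labels":
        ids = list(spec.label_ids) + [parcellation.resolve(n) for n in spec.label_names]
        mask = labels_to_mask(parcellation, ids)
    elif spec.kind == "box":
        mask = box_mask(parcellation.grid, spec.corners_mm)
    elif spec.kind == "midsagittal":
        mask = midsagittal_mask(parcellation.grid, spec.thickness_mm)
    elif spec.kind == "dilated":
        mask = dilate_mask(materialize_spec(spec.base, parcellation), spec.iterations)
    else:  # pragma: no cover - kinds validated at parse time
        raise MaterializationError(f"unknown VOI kind {spec.kind!r}")
    return VOIMask(mask.data, mask.grid, provenance=spec)


def materialize(
    bundle_def: BundleDefinition, parcellation: ParcellationVolume
) -> tuple[list[VOIMask], list[VOIMask], list[VOIMask]]:
    """Materialize a bundle definition's include/exclude/endpoint VOIs."""

    def _do(specs, role):
        out = []
        for i, spec in enumerate(specs):
            try:
                out.append(materialize_spec(spec, parcellation))
            except MaterializationError as exc:
                raise MaterializationError(
                    f"bundle {bundle_def.name!r}, {role} VOI #{i}: {exc}"
                ) from exc
        return out

    return (
        _do(bundle_def.includes, "include"),
        _do(bundle_def.excludes, "exclude"),
        _do(bundle_def.endpoint_includes, "endpoint"),
    )
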