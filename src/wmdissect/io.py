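"""Streamline and volume I/O plus the world<->voxel coordinate contract.

All computation elsewhere in the package happens in world RAS+ millimetre
coordinates; the on-disk quirks of TRK (corner-origin voxel-mm) and TCK are
confined to this module via :mod:`nibabel.streamlines`.

Voxel convention: 0-based indices, voxel-center cells. A world point maps to
index ``i`` along an axis iff its continuous voxel coordinate lies in
``[i - 0.5, i + 0.5)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import nibabel.streamlines as nbs
import numpy as np

__all__ = [
    "FormatError",
    "ReferenceGrid",
    "Tractogram",
    "read_tractogram",
    "write_tractogram",
    "read_volume",
    "write_volume",
    "world_to_voxel",
    "voxel_to_world",
]


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


@dataclass(frozen=True)
class ReferenceGrid:
    """A 3-D voxel grid: shape plus a voxel-index -> world-mm affine (RAS+)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def __eq__(self, other) -> bool:  # dataclass eq fails on ndarray
        if not isinstance(other, ReferenceGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def __hash__(self):
        return hash((self.shape, self.affine.tobytes()))


@dataclass
class Tractogram:
    """Ordered streamlines (world RAS+ mm) with an optional reference grid.

    Each streamline is an ``(n, 3)`` float array with ``n >= 2``.
    """

    streamlines: list[np.ndarray] = field(default_factory=list)
    grid: ReferenceGrid | None = None

    def __post_init__(self) -> None:
        cleaned = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(f"streamline {i} must be (n>=2, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def subset(self, indices) -> "Tractogram":
        return Tractogram([self.streamlines[i] for i in indices], grid=self.grid)


def _default_trk_header(grid: ReferenceGrid) -> dict:
    return {
        "voxel_to_rasmm": grid.affine.astype(np.float32),
        "dimensions": np.asarray(grid.shape, dtype=np.int16),
        "voxel_sizes": grid.voxel_sizes.astype(np.float32),
        "voxel_order": "".join(nib.aff2axcodes(grid.affine)),
    }


def read_tractogram(path: str | os.PathLike, reference: ReferenceGrid | None = None) -> Tractogram:
    """Read a TCK or TRK file into world RAS+ mm coordinates.

    TRK files carry their own reference grid in the header; TCK files do not,
    so ``reference`` (if given) supplies the grid.
    """
    try:
        tfile = nbs.load(str(path))
    except Exception as exc:  # nibabel raises various header errors
        raise FormatError(f"cannot read tractogram {path!r}: {exc}") from exc

    grid = reference
    if isinstance(tfile, nbs.trk.TrkFile):
        affine = np.asarray(tfile.header["voxel_to_rasmm"], dtype=float)
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise FormatError(f"TRK header affine of {path!r} is not invertible")
        grid = ReferenceGrid(tuple(int(d) for d in tfile.header["dimensions"]), affine)
    streamlines = [np.asarray(s, dtype=float) for s in tfile.streamlines]
    return Tractogram(streamlines, grid=grid)


def write_tractogram(tractogram: Tractogram, path: str | os.PathLike, format: str | None = None) -> None:
    """Write streamlines as TCK or TRK (inferred from the extension by default)."""
    path = str(path)
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").upper()
    format = format.upper()
    if format not in ("TCK", "TRK"):
        raise ValueError(f"unsupported tractogram format {format!r}")
    nbt = nbs.Tractogram(
        [s.astype(np.float32) for s in tractogram.streamlines], affine_to_rasmm=np.eye(4)
    )
    if format == "TRK":
        if tractogram.grid is None:
            raise ValueError("writing TRK requires a tractogram with a reference grid")
        nbs.save(nbt, path, header=_default_trk_header(tractogram.grid))
    else:
        nbs.save(nbt, path)


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, ReferenceGrid]:
    """Read a 3-D NIfTI volume; returns ``(data, grid)``."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got {data.ndim}-D in {path!r}")
    return data, ReferenceGrid(data.shape, img.affine)


def write_volume(data: np.ndarray, grid: ReferenceGrid, path: str | os.PathLike) -> None:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("volume data must be 3-D")
    if tuple(data.shape) != grid.shape:
        raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))


def world_to_voxel(points: np.ndarray, grid: ReferenceGrid) -> tuple[np.ndarray, np.ndarray]:
    """Map world-mm points to voxel indices (voxel-center, half-open cells).

    Returns ``(indices, in_grid)`` — indices are not clamped; ``in_grid``
    flags which points fall inside the grid bounds.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = grid.inverse_affine
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    idx = np.floor(vox + 0.5).astype(np.int64)  # [i-0.5, i+0.5) cell
    shape = np.asarray(grid.shape)
    in_grid = np.all((idx >= 0) & (idx < shape), axis=1)
    return idx, in_grid


def voxel_to_world(indices: np.ndarray, grid: ReferenceGrid) -> np.ndarray:
    """Map voxel indices to the world-mm coordinates of their centers."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    return idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
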