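"""Bundle segmentation: VOI-based streamline selection, filtering, smoothing.

Selection semantics: a streamline is retained iff it intersects ALL include
masks, NO exclude mask, and — when endpoint VOIs are set — has a terminal
point inside each endpoint mask. Intersection is decided on an arc-length
resampling of the polyline at spacing <= ``step_mm`` (default: half the
smallest voxel dimension, to prevent tunneling through thin masks).

A dissection fails when fewer than ``min_streamlines`` (default 10) survive
selection, or fewer than ``min_streamlines`` survive the first filtering step
(the length filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ReferenceGrid, Tractogram, world_to_voxel
from .registry import BundleDefinition, BundleRegistry
from .voi import MaterializationError, ParcellationVolume, VOIMask, materialize

__all__ = [
    "DissectionResult",
    "streamline_length",
    "resample_polyline",
    "streamline_intersects",
    "select_bundle",
    "flag_failure",
    "filter_length",
    "filter_outliers",
    "smooth_streamlines",
    "dissect_all",
    "default_step_mm",
]


def default_step_mm(grid: ReferenceGrid) -> float:
    """Default sampling step: half the smallest voxel dimension."""
    return float(np.min(grid.voxel_sizes)) / 2.0


def streamline_length(points: np.ndarray) -> float:
    """Polyline arc length (summed segment norms), in mm."""
    pts = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_polyline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline by arc length at spacing <= ``step_mm``.

    Endpoints are always included; samples lie exactly on the polyline.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be > 0")
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        return pts[[0, -1]]
    n_samples = int(np.ceil(total / step_mm)) + 1
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, total, n_samples)
    out = np.empty((n_samples, 3))
    for d in range(3):
        out[:, d] = np.interp(t, s, pts[:, d])
    return out


def _samples_in_mask(samples: np.ndarray, mask: VOIMask) -> np.ndarray:
    idx, in_grid = world_to_voxel(samples, mask.grid)
    hit = np.zeros(len(samples), dtype=bool)
    if in_grid.any():
        ig = idx[in_grid]
        hit[in_grid] = mask.data[ig[:, 0], ig[:, 1], ig[:, 2]]
    return hit


def streamline_intersects(streamline: np.ndarray, mask: VOIMask, step_mm: float) -> bool:
    """True iff any arc-length sample of the polyline falls in a true voxel."""
    samples = resample_polyline(streamline, step_mm)
    return bool(_samples_in_mask(samples, mask).any())


def _endpoint_in_mask(streamline: np.ndarray, mask: VOIMask) -> bool:
    ends = np.asarray(streamline)[[0, -1]]
    return bool(_samples_in_mask(ends, mask).any())


def flag_failure(initial_count: int, post_filter_count: int, min_streamlines: int = 10) -> bool:
    """Failure rule: too few streamlines initially or after the first filter."""
    if initial_count < 0 or post_filter_count < 0:
        raise ValueError("counts must be >= 0")
    return initial_count < min_streamlines or post_filter_count < min_streamlines


def filter_length(bundle: Tractogram, min_mm: float, max_mm: float) -> Tractogram:
    """Keep streamlines with arc length in the closed interval [min, max]."""
    if not (0 <= min_mm < max_mm):
        raise ValueError("need 0 <= min_mm < max_mm")
    keep = [i for i, s in enumerate(bundle) if min_mm <= streamline_length(s) <= max_mm]
    return bundle.subset(keep)


def _mean_closest_point(a: np.ndarray, b: np.ndarray) -> float:
    # symmetric mean closest-point distance; set-based, so inherently
    # invariant to flipping either streamline's point order
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def filter_outliers(bundle: Tractogram, z_threshold: float = 2.0, n_points: int = 32) -> Tractogram:
    """Reject streamlines far from the bundle medoid.

    Each streamline is resampled to ``n_points``; the medoid minimizes the
    summed symmetric mean closest-point distance to all others (computed
    orientation-invariantly). Streamlines whose distance to the medoid
    exceeds ``mean + z_threshold * stdev`` are removed. Bundles with fewer
    than 3 streamlines pass through unchanged.
    """
    n = len(bundle)
    if n < 3:
        return bundle.subset(range(n))
    res = [_resample_to_n(s, n_points) for s in bundle]
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = min(
                _mean_closest_point(res[i], res[j]),
                _mean_closest_point(res[i][::-1], res[j]),
            )
            dmat[i, j] = dmat[j, i] = dij
    medoid = int(np.argmin(dmat.sum(axis=1)))
    dist = dmat[medoid]
    mu, sd = dist.mean(), dist.std()
    if sd == 0:
        return bundle.subset(range(n))
    keep = [i for i in range(n) if dist[i] <= mu + z_threshold * sd]
    return bundle.subset(keep)


def _resample_to_n(points: np.ndarray, n: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if total == 0:
        return np.repeat(pts[:1], n, axis=0)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(t, s, pts[:, d])
    return out


def smooth_streamlines(bundle: Tractogram, window: int = 3) -> Tractogram:
    """Centered moving average over each point sequence; endpoints fixed.

    The window shrinks symmetrically near the sequence ends, so straight
    lines are left exactly unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window == 1:
        return bundle.subset(range(len(bundle)))
    half = window // 2
    out = []
    for s in bundle:
        n = len(s)
        sm = s.copy()
        for i in range(1, n - 1):
            h = min(half, i, n - 1 - i)  # symmetric window, shrunk at ends
            sm[i] = s[i - h : i + h + 1].mean(axis=0)
        out.append(sm)
    return Tractogram(out, grid=bundle.grid)


@dataclass
class DissectionResult:
    bundle_name: str
    selected: Tractogram
    counts: dict = field(default_factory=dict)
    failed: bool = False
    failure_reason: str | None = None
    error: str | None = None


def select_bundle(
    tractogram: Tractogram,
    bundle_def: BundleDefinition,
    parcellation: ParcellationVolume,
    step_mm: float | None = None,
    smooth_window: int = 1,
) -> DissectionResult:
    """Dissect one bundle from a whole-brain tractogram.

    Stages: VOI selection -> length filter -> statistical outlier filter ->
    smoothing; per-stage counts and the failure flag are recorded.
    """
    if step_mm is None:
        step_mm = default_step_mm(parcellation.grid)
    includes, excludes, endpoints = materialize(bundle_def, parcellation)

    keep = []
    for i, s in enumerate(tractogram):
        samples = resample_polyline(s, step_mm)
        if not all(_samples_in_mask(samples, m).any() for m in includes):
            continue
        if any(_samples_in_mask(samples, m).any() for m in excludes):
            continue
        if endpoints and not all(_endpoint_in_mask(s, m) for m in endpoints):
            continue
        keep.append(i)
    selected = tractogram.subset(keep)
    n_selected = len(selected)

    if bundle_def.length_bounds_mm is not None:
        lo, hi = bundle_def.length_bounds_mm
        selected = filter_length(selected, lo, hi)
    n_length = len(selected)

    failed = flag_failure(n_selected, n_length, bundle_def.min_streamlines)
    reason = None
    if failed:
        if n_selected < bundle_def.min_streamlines:
            reason = (
                f"{n_selected} streamlines selected initially "
                f"(< {bundle_def.min_streamlines})"
            )
        else:
            reason = (
                f"{n_length} streamlines after first filtering step "
                f"(< {bundle_def.min_streamlines})"
            )

    if bundle_def.outlier_z is not None:
        selected = filter_outliers(selected, bundle_def.outlier_z)
    n_final = len(selected)

    if smooth_window > 1 and n_final:
        selected = smooth_streamlines(selected, smooth_window)

    counts = {
        "initial_candidates": len(tractogram),
        "after_selection": n_selected,
        "after_filtering": n_final,
    }
    return DissectionResult(
        bundle_name=bundle_def.name,
        selected=selected,
        counts=counts,
        failed=failed,
        failure_reason=reason,
    )


def dissect_all(
    tractogram: Tractogram,
    registry: BundleRegistry,
    parcellation: ParcellationVolume,
    step_mm: float | None = None,
    smooth_window: int = 1,
) -> list[DissectionResult]:
    """Run every registry definition against the tractogram.

    Per-bundle errors (e.g. unresolvable labels) are collected on the result,
    not raised, so one broken definition cannot abort a run.
    """
    results = []
    for bdef in registry:
        try:
            results.append(
                select_bundle(tractogram, bdef, parcellation, step_mm=step_mm, smooth_window=smooth_window)
            )
        except MaterializationError as exc:
            results.append(
                DissectionResult(
                    bundle_name=bdef.name,
                    selected=Tractogram([], grid=tractogram.grid),
                    counts={"initial_candidates": len(tractogram), "after_selection": 0, "after_filtering": 0},
                    failed=True,
                    failure_reason="materialization error",
                    error=str(exc),
                )
            )
    return results
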