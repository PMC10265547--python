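"""Synthetic streamline phantoms.

Generates miniature parcellations (labeled box regions on a centered grid)
and geometric streamline bundles (parametric centerlines plus Gaussian radial
jitter), with test-retest replication and optional distractor streamlines.
These scenes stand in for real whole-brain data when exercising dissection,
density mapping and the reproducibility metrics.

Determinism: every generator takes a seed; identical seeds give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ReferenceGrid, Tractogram
from .registry import (
    REGION_VOCABULARY,
    BundleDefinition,
    BundleRegistry,
    VOISpec,
)
from .voi import ParcellationVolume

__all__ = [
    "Region",
    "BundlePlan",
    "PhantomSpec",
    "Scene",
    "make_grid",
    "make_parcellation",
    "centerline_points",
    "make_bundle",
    "make_scene",
    "make_testretest",
    "scene_registry",
    "demo_spec",
    "atlas_spec",
]

CENTERLINE_KINDS = ("straight", "arc", "helix", "commissural_u")


@dataclass(frozen=True)
class Region:
    """Axis-aligned box region: world-mm center and half-extent."""

    name: str
    center_mm: tuple[float, float, float]
    half_mm: float = 4.0


@dataclass(frozen=True)
class BundlePlan:
    name: str
    centerline: str = "straight"
    n_streamlines: int = 100
    radial_jitter_mm: float = 1.0
    start_region: str = ""
    end_region: str = ""
    via_regions: tuple[str, ...] = ()
    amplitude_mm: float = 8.0
    n_points: int = 50
    group: str = "association"
    hemisphere: str = "left"

    def __post_init__(self):
        if self.centerline not in CENTERLINE_KINDS:
            raise ValueError(f"unknown centerline kind {self.centerline!r}")
        if self.n_streamlines < 0 or self.radial_jitter_mm < 0:
            raise ValueError("n_streamlines and radial_jitter_mm must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 2.0
    regions: tuple[Region, ...] = ()
    bundles: tuple[BundlePlan, ...] = ()
    n_distractors: int = 0
    seed: int = 0

    def __post_init__(self):
        names = [r.name for r in self.regions]
        if len(names) != len(set(names)):
            raise ValueError("region names must be distinct")
        known = set(names)
        for b in self.bundles:
            for rn in (b.start_region, b.end_region, *b.via_regions):
                if rn not in known:
                    raise ValueError(f"bundle {b.name!r} references unknown region {rn!r}")

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


def make_grid(spec: PhantomSpec) -> ReferenceGrid:
    """Centered RAS+ grid: world origin at the grid center."""
    vs = float(spec.voxel_size_mm)
    shape = np.asarray(spec.shape)
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -(shape - 1) / 2.0 * vs
    return ReferenceGrid(tuple(int(s) for s in shape), affine)


def make_parcellation(spec: PhantomSpec) -> ParcellationVolume:
    """Label volume with one box region per declared region, background 0.

    Labels are assigned 1..N in declaration order; overlapping region
    requests raise.
    """
    grid = make_grid(spec)
    data = np.zeros(grid.shape, dtype=np.int32)
    labels: dict[str, int] = {}
    inv = grid.inverse_affine
    for lab, region in enumerate(spec.regions, start=1):
        c = np.asarray(region.center_mm, dtype=float)
        lo_w, hi_w = c - region.half_mm, c + region.half_mm
        lo_v = (lo_w @ inv[:3, :3].T + inv[:3, 3])
        hi_v = (hi_w @ inv[:3, :3].T + inv[:3, 3])
        # voxel centers inside the closed world box (same rule as box_mask)
        lo_i = np.maximum(np.ceil(np.minimum(lo_v, hi_v) - 1e-9), 0).astype(int)
        hi_i = np.minimum(np.floor(np.maximum(lo_v, hi_v) + 1e-9), np.asarray(grid.shape) - 1).astype(int)
        if np.any(hi_i < lo_i):
            raise ValueError(f"region {region.name!r} lies outside the grid")
        block = data[lo_i[0] : hi_i[0] + 1, lo_i[1] : hi_i[1] + 1, lo_i[2] : hi_i[2] + 1]
        if np.any(block != 0):
            raise ValueError(f"region {region.name!r} overlaps a previously placed region")
        block[...] = lab
        labels[region.name] = lab
    return ParcellationVolume(data, grid, labels=labels)


def _perp_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def centerline_points(spec: PhantomSpec, plan: BundlePlan) -> np.ndarray:
    """Parametric centerline through the plan's anchor-region centers."""
    anchors = np.array(
        [spec.region(n).center_mm for n in (plan.start_region, *plan.via_regions, plan.end_region)],
        dtype=float,
    )
    # base: piecewise-linear through anchors, resampled uniformly by arc length
    seg = np.linalg.norm(np.diff(anchors, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], plan.n_points)
    base = np.column_stack([np.interp(t, s, anchors[:, d]) for d in range(3)])
    if plan.centerline == "straight":
        return base
    axis = anchors[-1] - anchors[0]
    u, v = _perp_basis(axis)
    tau = np.linspace(0.0, 1.0, plan.n_points)
    bulge = plan.amplitude_mm * np.sin(np.pi * tau)
    if plan.centerline == "arc":
        return base + bulge[:, None] * u
    if plan.centerline == "commissural_u":
        # vertical arch, e.g. callosal fibers crossing the midline
        up = np.array([0.0, 0.0, 1.0])
        if abs((axis / np.linalg.norm(axis)) @ up) > 0.9:
            up = np.array([0.0, 1.0, 0.0])
        return base + bulge[:, None] * up
    # helix: rotating perturbation, pinned at the endpoints
    turns = 2.0
    ang = 2.0 * np.pi * turns * tau
    return base + bulge[:, None] * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)


def make_bundle(
    centerline: np.ndarray,
    n_streamlines: int,
    jitter: float,
    seed: int,
    grid: ReferenceGrid | None = None,
) -> Tractogram:
    """Bundle = centerline copies plus Gaussian radial offsets (sd = jitter).

    Each streamline gets one rigid offset: a uniformly random direction in
    the plane perpendicular to the bundle axis, scaled by a N(0, jitter)
    draw, so the point-to-centerline distance is half-normal.
    """
    rng = np.random.default_rng(seed)
    cl = np.asarray(centerline, dtype=float)
    axis = cl[-1] - cl[0]
    if np.linalg.norm(axis) == 0:
        axis = np.array([1.0, 0.0, 0.0])
    u, v = _perp_basis(axis)
    streamlines = []
    for _ in range(n_streamlines):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        r = rng.normal(0.0, jitter) if jitter > 0 else 0.0
        offset = r * (np.cos(theta) * u + np.sin(theta) * v)
        streamlines.append(cl + offset)
    return Tractogram(streamlines, grid=grid)


def _make_distractors(spec: PhantomSpec, grid: ReferenceGrid, rng: np.random.Generator) -> list[np.ndarray]:
    """Random smooth curves that avoid every declared region box."""
    extent_lo = grid.affine[:3, 3]
    extent_hi = extent_lo + (np.asarray(grid.shape) - 1) * grid.voxel_sizes
    # margin: half the voxel diagonal, so no point can sit in a labeled voxel
    margin = float(np.linalg.norm(grid.voxel_sizes) / 2.0) + 0.5
    boxes = [
        (np.asarray(r.center_mm) - r.half_mm - margin, np.asarray(r.center_mm) + r.half_mm + margin)
        for r in spec.regions
    ]

    def hits_region(pts):
        for lo, hi in boxes:
            if np.any(np.all((pts >= lo) & (pts <= hi), axis=1)):
                return True
        return False

    out = []
    attempts = 0
    while len(out) < spec.n_distractors and attempts < spec.n_distractors * 200 + 200:
        attempts += 1
        p0, p1, pc = (rng.uniform(extent_lo, extent_hi) for _ in range(3))
        tau = np.linspace(0.0, 1.0, 60)[:, None]
        pts = (1 - tau) ** 2 * p0 + 2 * tau * (1 - tau) * pc + tau**2 * p1  # quadratic Bezier
        if not hits_region(pts):
            out.append(pts)
    return out


@dataclass
class Scene:
    """A generated phantom: parcellation, whole tractogram, ground truth."""

    spec: PhantomSpec
    parcellation: ParcellationVolume
    tractogram: Tractogram
    membership: list[str]  # per-streamline bundle name, or "distractor"

    @property
    def grid(self) -> ReferenceGrid:
        return self.parcellation.grid

    def bundle_indices(self, name: str) -> list[int]:
        return [i for i, m in enumerate(self.membership) if m == name]


def make_scene(spec: PhantomSpec, seed: int | None = None) -> Scene:
    """Generate a full phantom scene; seed defaults to ``spec.seed``."""
    if seed is None:
        seed = spec.seed
    parcellation = make_parcellation(spec)
    grid = parcellation.grid
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(spec.bundles) + 1)
    streamlines: list[np.ndarray] = []
    membership: list[str] = []
    for plan, child in zip(spec.bundles, child_seeds):
        cl = centerline_points(spec, plan)
        bundle = make_bundle(
            cl, plan.n_streamlines, plan.radial_jitter_mm,
            seed=child.generate_state(1)[0], grid=grid,
        )
        streamlines.extend(bundle.streamlines)
        membership.extend([plan.name] * len(bundle))
    rng = np.random.default_rng(child_seeds[-1].generate_state(1)[0])
    distractors = _make_distractors(spec, grid, rng)
    streamlines.extend(distractors)
    membership.extend(["distractor"] * len(distractors))
    return Scene(spec, parcellation, Tractogram(streamlines, grid=grid), membership)


def make_testretest(spec: PhantomSpec, seed_pair: tuple[int, int]) -> tuple[Scene, Scene]:
    """Two sessions with identical geometry and independent jitter draws."""
    s1, s2 = seed_pair
    if s1 == s2:
        raise ValueError("test-retest sessions need distinct seeds")
    return make_scene(spec, seed=s1), make_scene(spec, seed=s2)


def scene_registry(spec: PhantomSpec) -> BundleRegistry:
    """Dissection registry matching a phantom's planted bundles."""
    defs = []
    for plan in spec.bundles:
        includes = tuple(
            VOISpec(kind="labels", label_names=(rn,))
            for rn in (plan.start_region, *plan.via_regions, plan.end_region)
        )
        defs.append(
            BundleDefinition(
                name=plan.name,
                group=plan.group,
                hemisphere=plan.hemisphere,
                includes=includes,
            )
        )
    return BundleRegistry(defs, version="phantom")


def demo_spec(
    n_dense: int = 500, n_sparse: int = 25, jitter: float = 1.5, n_distractors: int = 40, seed: int = 0
) -> PhantomSpec:
    """Four-bundle demo scene: dense straight, arc, commissural arch, sparse.

    The dense/sparse pair mimics the density contrast between a large
    projection bundle and a thin limbic one.
    """
    regions = (
        Region("motor_seed", (-20.0, 0.0, 28.0), 6.0),
        Region("stem_seed", (-6.0, 0.0, -28.0), 6.0),
        Region("frontal_seed", (-24.0, 30.0, 0.0), 6.0),
        Region("temporal_seed", (-24.0, -30.0, 0.0), 6.0),
        Region("ctx_left", (-26.0, 0.0, 6.0), 5.0),
        Region("ctx_right", (26.0, 0.0, 6.0), 5.0),
        Region("hc_seed", (20.0, -30.0, -12.0), 5.0),
        Region("th_seed", (20.0, 24.0, -12.0), 5.0),
    )
    bundles = (
        BundlePlan(
            name="dense_straight", centerline="straight", n_streamlines=n_dense,
            radial_jitter_mm=jitter, start_region="motor_seed", end_region="stem_seed",
            group="projection",
        ),
        BundlePlan(
            name="arcuate_like", centerline="arc", n_streamlines=200,
            radial_jitter_mm=jitter, start_region="frontal_seed", end_region="temporal_seed",
            amplitude_mm=10.0,
        ),
        BundlePlan(
            name="callosal_like", centerline="commissural_u", n_streamlines=150,
            radial_jitter_mm=jitter, start_region="ctx_left", end_region="ctx_right",
            amplitude_mm=14.0, group="commissural", hemisphere="midline",
        ),
        BundlePlan(
            name="sparse_arc", centerline="arc", n_streamlines=n_sparse,
            radial_jitter_mm=jitter, start_region="hc_seed", end_region="th_seed",
            amplitude_mm=8.0,
        ),
    )
    return PhantomSpec(
        shape=(40, 48, 40), voxel_size_mm=2.0, regions=regions,
        bundles=bundles, n_distractors=n_distractors, seed=seed,
    )


# ---------------------------------------------------------------------------
# Atlas phantom: binds the full symbolic region vocabulary of the default
# registry to concrete positions, so every default bundle definition
# materializes on it.
# ---------------------------------------------------------------------------

_ATLAS_LAYOUT: dict[str, tuple[tuple[float, float, float], float]] = {
    # stem name -> (center for the right hemisphere (+x), half-extent mm)
    "prefrontal": ((16.0, 40.0, 10.0), 5.0),
    "frontal": ((28.0, 28.0, 10.0), 5.0),
    "premotor": ((24.0, 12.0, 34.0), 5.0),
    "sma": ((8.0, 12.0, 44.0), 4.0),
    "motor": ((24.0, 0.0, 38.0), 5.0),
    "sensory": ((24.0, -12.0, 38.0), 4.0),
    "parietal": ((24.0, -30.0, 30.0), 5.0),
    "occipital": ((16.0, -48.0, 2.0), 5.0),
    "temporal": ((36.0, -16.0, -10.0), 4.0),
    "temporal_pole": ((28.0, 16.0, -14.0), 4.0),
    "cingulate_ant": ((6.0, 24.0, 20.0), 3.0),
    "cingulate_post": ((6.0, -24.0, 22.0), 3.0),
    "hippocampus": ((24.0, -22.0, -14.0), 3.0),
    "thalamus": ((10.0, -12.0, 6.0), 3.0),
    "lgn": ((20.0, -24.0, 0.0), 2.0),
    "red_nucleus": ((4.0, -18.0, -6.0), 2.0),
    "dentate": ((12.0, -52.0, -26.0), 2.0),
    "cerebellum": ((24.0, -52.0, -32.0), 4.0),
    "pons": ((4.0, -26.0, -22.0), 3.0),
    "medulla": ((4.0, -30.0, -36.0), 3.0),
}

_ATLAS_MIDLINE: dict[str, tuple[tuple[float, float, float], float]] = {
    "optic_chiasm": ((0.0, 6.0, -6.0), 2.5),
}


def atlas_regions() -> tuple[Region, ...]:
    regions = []
    for stem, (center, half) in _ATLAS_LAYOUT.items():
        x, y, z = center
        regions.append(Region(f"{stem}_l", (-x, y, z), half))
        regions.append(Region(f"{stem}_r", (x, y, z), half))
    for name, (center, half) in _ATLAS_MIDLINE.items():
        regions.append(Region(name, center, half))
    assert {r.name for r in regions} == set(REGION_VOCABULARY)
    return tuple(regions)


def atlas_spec(
    bundles: tuple[BundlePlan, ...] = (), n_distractors: int = 0, seed: int = 0
) -> PhantomSpec:
    """Phantom spec whose parcellation covers the full region vocabulary."""
    return PhantomSpec(
        shape=(48, 64, 56), voxel_size_mm=2.0, regions=atlas_regions(),
        bundles=bundles, n_distractors=n_distractors, seed=seed,
    )


def atlas_demo_bundles(n_streamlines: int = 150, jitter: float = 1.0) -> tuple[BundlePlan, ...]:
    """A few planted bundles that match default-registry definitions."""
    return (
        BundlePlan(
            name="ATR_left", centerline="straight", n_streamlines=n_streamlines,
            radial_jitter_mm=jitter, start_region="prefrontal_l", end_region="thalamus_l",
            group="projection",
        ),
        BundlePlan(
            name="ILF_right", centerline="arc", n_streamlines=n_streamlines,
            radial_jitter_mm=jitter, start_region="temporal_pole_r", end_region="occipital_r",
            amplitude_mm=6.0, hemisphere="right",
        ),
        BundlePlan(
            name="CC_Motor", centerline="commissural_u", n_streamlines=n_streamlines,
            radial_jitter_mm=jitter, start_region="motor_l", end_region="motor_r",
            amplitude_mm=10.0, group="commissural", hemisphere="midline",
        ),
        BundlePlan(
            name="FX_left", centerline="arc", n_streamlines=max(n_streamlines // 10, 12),
            radial_jitter_mm=jitter, start_region="hippocampus_l", end_region="thalamus_l",
            amplitude_mm=6.0,
        ),
    )
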