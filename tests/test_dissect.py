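import numpy as np
import pytest

from wmdissect.dissect import (
    default_step_mm,
    dissect_all,
    filter_length,
    filter_outliers,
    flag_failure,
    resample_polyline,
    select_bundle,
    smooth_streamlines,
    streamline_intersects,
    streamline_length,
)
from wmdissect.io import ReferenceGrid, Tractogram
from wmdissect.registry import BundleDefinition, BundleRegistry, VOISpec
from wmdissect.voi import ParcellationVolume, VOIMask


def single_voxel_mask(grid, idx):
    data = np.zeros(grid.shape, dtype=bool)
    data[idx] = True
    return VOIMask(data, grid)


class TestStreamlineIntersects:
    def test_straight_crossing_slab(self, identity_grid):
        data = np.zeros((16, 16, 16), dtype=bool)
        data[8, :, :] = True
        mask = VOIMask(data, identity_grid)
        s = np.array([[2.0, 5, 5], [14.0, 5, 5]])
        assert streamline_intersects(s, mask, step_mm=0.5)

    def test_outside_grid_false(self, identity_grid):
        mask = VOIMask(np.ones((16, 16, 16), dtype=bool), identity_grid)
        s = np.array([[-30.0, -30, -30], [-20.0, -20, -20]])
        assert not streamline_intersects(s, mask, step_mm=0.5)

    def test_step_size_controls_tunneling(self, identity_grid):
        # diagonal segment through voxel (5,5,5): endpoints land in the
        # adjacent voxels, so step=2 samples only the endpoints and misses,
        # while step=0.5 samples inside the voxel
        mask = single_voxel_mask(identity_grid, (5, 5, 5))
        s = np.array([[4.4, 4.4, 5.0], [5.6, 5.6, 5.0]])
        assert not streamline_intersects(s, mask, step_mm=2.0)
        assert streamline_intersects(s, mask, step_mm=0.5)

    def test_default_step_half_min_voxel(self):
        grid = ReferenceGrid((4, 4, 4), np.diag([1.25, 2.5, 2.0, 1.0]))
        assert default_step_mm(grid) == pytest.approx(0.625)


class TestResample:
    def test_endpoints_kept(self):
        s = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        r = resample_polyline(s, 3.0)
        np.testing.assert_allclose(r[0], s[0])
        np.testing.assert_allclose(r[-1], s[-1])
        gaps = np.linalg.norm(np.diff(r, axis=0), axis=1)
        assert (gaps <= 3.0 + 1e-12).all()

    def test_samples_lie_on_polyline(self):
        s = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 2.0, 0]])
        r = resample_polyline(s, 0.3)
        # every sample is on one of the two segments
        on_first = (np.abs(r[:, 1]) < 1e-12) & (r[:, 0] >= -1e-12) & (r[:, 0] <= 1 + 1e-12)
        on_second = (np.abs(r[:, 0] - 1) < 1e-12) & (r[:, 1] >= -1e-12) & (r[:, 1] <= 2 + 1e-12)
        assert (on_first | on_second).all()


class TestFlagFailure:
    def test_boundary_below(self):
        assert flag_failure(9, 9, 10) is True

    def test_boundary_at_threshold(self):
        assert flag_failure(10, 10, 10) is False

    def test_zero_counts(self):
        assert flag_failure(0, 0, 10) is True

    def test_post_filter_triggers(self):
        assert flag_failure(50, 9, 10) is True

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            flag_failure(-1, 5, 10)


class TestFilterLength:
    def test_unbounded_identity(self, identity_grid):
        t = Tractogram([np.array([[0.0, 0, 0], [3.0, 0, 0]])], grid=identity_grid)
        assert len(filter_length(t, 0, np.inf)) == 1

    def test_removes_short_streamline(self):
        # 10 mm straight line vs bounds (11, 20)
        t = Tractogram([np.array([[0.0, 0, 0], [10.0, 0, 0]])])
        assert len(filter_length(t, 11, 20)) == 0

    def test_empty_input(self):
        assert len(filter_length(Tractogram([]), 0, 10)) == 0

    def test_arc_length_summed_segments(self):
        s = np.array([[0.0, 0, 0], [3.0, 0, 0], [3.0, 4.0, 0]])
        assert streamline_length(s) == pytest.approx(7.0)


class TestFilterOutliers:
    def test_identical_streamlines_none_removed(self):
        s = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        t = Tractogram([s.copy() for _ in range(20)])
        assert len(filter_outliers(t, z_threshold=2.0)) == 20

    def test_offset_streamline_removed(self):
        rng = np.random.default_rng(0)
        base = np.column_stack([np.linspace(0, 50, 20), np.zeros(20), np.zeros(20)])
        sls = [base + np.array([0.0, rng.uniform(-1, 1), rng.uniform(-1, 1)]) for _ in range(19)]
        sls.append(base + np.array([0.0, 50.0, 0.0]))
        kept = filter_outliers(Tractogram(sls), z_threshold=2.0)
        assert len(kept) == 19
        # brute-force distance vector confirms only the offset one is far
        assert all(abs(s[0, 1]) < 2 for s in kept)

    def test_brute_force_distance_agrees(self):
        # hand-computed: distances of parallel straight lines to the medoid
        # equal their perpendicular offsets
        offsets = [0.0, 0.1, -0.2, 0.15, 8.0]
        base = np.column_stack([np.linspace(0, 30, 10), np.zeros(10), np.zeros(10)])
        sls = [base + np.array([0.0, o, 0.0]) for o in offsets]
        d = np.abs(np.array(offsets))  # distance to medoid (offset 0.0)
        mu, sd = d.mean(), d.std()
        expect_removed = {i for i, v in enumerate(d) if v > mu + 1.5 * sd}
        kept = filter_outliers(Tractogram(sls), z_threshold=1.5)
        kept_offsets = {round(float(s[0, 1]), 6) for s in kept}
        assert kept_offsets == {round(offsets[i], 6) for i in range(5) if i not in expect_removed}

    def test_below_minimum_identity(self):
        t = Tractogram([np.array([[0.0, 0, 0], [1.0, 0, 0]]), np.array([[5.0, 5, 5], [9.0, 9, 9]])])
        assert len(filter_outliers(t, 1.0)) == 2


class TestSmoothing:
    def test_window_one_identity(self):
        s = np.array([[0.0, 0, 0], [1.0, 1, 0], [2.0, 0, 0]])
        t = smooth_streamlines(Tractogram([s]), window=1)
        np.testing.assert_array_equal(t.streamlines[0], s)

    def test_straight_line_unchanged(self):
        s = np.column_stack([np.linspace(0, 10, 11), np.zeros(11), np.zeros(11)])
        t = smooth_streamlines(Tractogram([s]), window=5)
        np.testing.assert_allclose(t.streamlines[0], s, atol=1e-12)

    def test_zigzag_window3_hand_average(self):
        a = 3.0
        y = np.array([0.0, a, 0.0, a, 0.0])
        s = np.column_stack([np.arange(5.0), y, np.zeros(5)])
        t = smooth_streamlines(Tractogram([s]), window=3)
        got = t.streamlines[0][:, 1]
        np.testing.assert_allclose(got, [0.0, a / 3, 2 * a / 3, a / 3, 0.0])
        # endpoints fixed
        np.testing.assert_array_equal(t.streamlines[0][[0, -1]], s[[0, -1]])

    def test_arc_length_change_bounded(self, demo_scene):
        for s in demo_scene.tractogram.streamlines[:20]:
            sm = smooth_streamlines(Tractogram([s]), window=5).streamlines[0]
            l0, l1 = streamline_length(s), streamline_length(sm)
            assert abs(l1 - l0) / l0 < 0.2

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_streamlines(Tractogram([]), window=4)


def toy_scene():
    """3 streamlines: include slab hit by #0,#1; exclude voxel hit by #1."""
    grid = ReferenceGrid((16, 16, 16), np.eye(4))
    data = np.zeros((16, 16, 16), dtype=np.int32)
    data[8, :, :] = 1  # include slab at x=8
    data[8, 8, 8] = 2  # exclude voxel inside the slab
    parc = ParcellationVolume(data, grid, labels={"inc": 1, "exc": 2})
    s0 = np.array([[2.0, 2, 2], [14.0, 2, 2]])  # crosses slab away from exclude
    s1 = np.array([[2.0, 8, 8], [14.0, 8, 8]])  # crosses slab through exclude
    s2 = np.array([[2.0, 2, 2], [2.0, 14, 2]])  # never reaches the slab
    t = Tractogram([s0, s1, s2], grid=grid)
    return t, parc


class TestSelectBundle:
    def test_three_streamline_toy(self):
        t, parc = toy_scene()
        bdef = BundleDefinition(
            name="toy", group="association", hemisphere="left",
            includes=(VOISpec(kind="labels", label_names=("inc",)),),
            excludes=(VOISpec(kind="labels", label_names=("exc",)),),
            min_streamlines=1,
        )
        res = select_bundle(t, bdef, parc)
        assert len(res.selected) == 1
        np.testing.assert_array_equal(res.selected.streamlines[0], t.streamlines[0])
        assert res.counts == {"initial_candidates": 3, "after_selection": 1, "after_filtering": 1}
        assert not res.failed

    def test_exclude_whole_grid_fails(self):
        t, parc = toy_scene()
        bdef = BundleDefinition(
            name="toy", group="association", hemisphere="left",
            includes=(VOISpec(kind="labels", label_names=("inc",)),),
            excludes=(VOISpec(kind="box", corners_mm=((-1, -1, -1), (16, 16, 16))),),
        )
        res = select_bundle(t, bdef, parc)
        assert len(res.selected) == 0
        assert res.failed and "initially" in res.failure_reason

    def test_endpoint_semantics(self):
        t, parc = toy_scene()
        # endpoint VOI at the start voxel of s0 only
        bdef = BundleDefinition(
            name="toy", group="association", hemisphere="left",
            includes=(VOISpec(kind="labels", label_names=("inc",)),),
            endpoint_includes=(VOISpec(kind="box", corners_mm=((1.6, 1.6, 1.6), (2.4, 2.4, 2.4))),),
            min_streamlines=1,
        )
        res = select_bundle(t, bdef, parc)
        assert len(res.selected) == 1
        np.testing.assert_array_equal(res.selected.streamlines[0], t.streamlines[0])

    def test_phantom_recovery_95_percent(self, demo_scene, demo_registry):
        bdef = demo_registry["dense_straight"]
        res = select_bundle(demo_scene.tractogram, bdef, demo_scene.parcellation)
        truth = set(demo_scene.bundle_indices("dense_straight"))
        sel_pts = {s.tobytes() for s in res.selected}
        truth_pts = {demo_scene.tractogram.streamlines[i].tobytes() for i in truth}
        distractors = {
            demo_scene.tractogram.streamlines[i].tobytes()
            for i in demo_scene.bundle_indices("distractor")
        }
        assert len(sel_pts & truth_pts) >= 0.95 * len(truth)
        assert not (sel_pts & distractors)

    def test_monotonicity_adding_masks(self):
        t, parc = toy_scene()
        inc = VOISpec(kind="labels", label_names=("inc",))
        base = BundleDefinition(name="b", group="association", hemisphere="left",
                                includes=(inc,), min_streamlines=1)
        more_inc = BundleDefinition(name="b", group="association", hemisphere="left",
                                    includes=(inc, VOISpec(kind="labels", label_names=("exc",))),
                                    min_streamlines=1)
        with_exc = BundleDefinition(name="b", group="association", hemisphere="left",
                                    includes=(inc,), excludes=(VOISpec(kind="labels", label_names=("exc",)),),
                                    min_streamlines=1)
        n_base = len(select_bundle(t, base, parc).selected)
        assert len(select_bundle(t, more_inc, parc).selected) <= n_base
        assert len(select_bundle(t, with_exc, parc).selected) <= n_base

    def test_idempotence_without_outlier_stage(self, demo_scene, demo_registry):
        bdef = demo_registry["arcuate_like"]
        assert bdef.outlier_z is None
        first = select_bundle(demo_scene.tractogram, bdef, demo_scene.parcellation)
        second = select_bundle(first.selected, bdef, demo_scene.parcellation)
        assert len(second.selected) == len(first.selected)

    def test_order_independence(self, demo_scene, demo_registry):
        bdef = demo_registry["sparse_arc"]
        fwd = select_bundle(demo_scene.tractogram, bdef, demo_scene.parcellation)
        perm = list(reversed(range(len(demo_scene.tractogram))))
        rev = select_bundle(demo_scene.tractogram.subset(perm), bdef, demo_scene.parcellation)
        fwd_set = {s.tobytes() for s in fwd.selected}
        rev_set = {s.tobytes() for s in rev.selected}
        assert fwd_set == rev_set


class TestDissectAll:
    def test_four_planted_bundles(self, demo_scene, demo_registry):
        results = dissect_all(demo_scene.tractogram, demo_registry, demo_scene.parcellation)
        assert len(results) == 4
        assert all(not r.failed for r in results)

    def test_empty_tractogram_all_failed(self, demo_scene, demo_registry):
        empty = Tractogram([], grid=demo_scene.grid)
        results = dissect_all(empty, demo_registry, demo_scene.parcellation)
        assert all(r.failed for r in results)

    def test_full_registry_on_partial_phantom_completes(self, demo_scene):
        # most of the 68 default definitions cannot resolve on the demo
        # parcellation; errors are collected per bundle, the run completes
        from wmdissect.registry import default_registry

        results = dissect_all(demo_scene.tractogram, default_registry(), demo_scene.parcellation)
        assert len(results) == 68
        assert all(r.failed for r in results)
        assert any(r.error for r in results)
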