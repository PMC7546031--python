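import numpy as np
import pytest

from isletmorph.segmentation import CellMask
from isletmorph.tracking import (
    CellTrack,
    distance_series,
    extract_centers,
    hull_volume,
    normalize_to_reference,
)

SP = (1.0, 0.3, 0.3)


def ball_mask_at(center_um, radius_um=2.0, shape=(24, 80, 80)):
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, SP)], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_um))
    return CellMask(d2 <= radius_um**2, SP)


def track_from_centers(cell_id, centers):
    centers = np.asarray(centers, float)
    return CellTrack(cell_id=cell_id, centers=centers, present=np.ones(len(centers), bool))


class TestExtractCenters:
    def test_sphere_centroid_within_half_voxel(self):
        tracks = extract_centers({"a": [ball_mask_at((10.0, 10.2, 10.2))]})
        assert np.all(np.abs(tracks[0].centers[0] - (10.0, 10.2, 10.2)) <= 0.5 * np.array(SP))

    def test_translated_mask_shifts_centroid_exactly(self):
        m0 = ball_mask_at((10.0, 9.0, 9.0))
        m1 = CellMask(np.roll(m0.data, (2, 10), axis=(0, 1)), SP)  # +2 μm z, +3 μm y
        tracks = extract_centers({"a": [m0, m1]})
        shift = tracks[0].centers[1] - tracks[0].centers[0]
        np.testing.assert_allclose(shift, (2.0, 3.0, 0.0), atol=1e-9)

    def test_absent_frames_flagged(self):
        tracks = extract_centers({"a": [ball_mask_at((10, 10, 10)), None]})
        assert tracks[0].present.tolist() == [True, False]

    def test_empty_present_mask_rejected(self):
        empty = CellMask(np.zeros((8, 8, 8), bool), SP)
        with pytest.raises(ValueError, match="empty mask"):
            extract_centers({"a": [empty]})

    def test_multi_cell_scene_matches_truth(self):
        from isletmorph.segmentation import hysteresis_segment, purify
        from isletmorph.synthetic import CellSpec, SceneSpec, render_scene

        centers = [(8.0, 6.0, 6.0), (8.0, 6.0, 18.0), (8.0, 18.0, 6.0), (8.0, 18.0, 18.0)]
        spec = SceneSpec(
            grid_shape=(16, 80, 80),
            cells=[CellSpec(center=c, semi_axes=(2.5, 2.5, 2.5)) for c in centers],
            psf_sigma=(0, 0, 0),
            seed=4,
        )
        img, truth = render_scene(spec)
        vol = img.volume()
        masks = {}
        for i, c in enumerate(centers):
            masks[i] = [ball_mask_at(c, 2.5, shape=vol.shape)]
        tracks = extract_centers(masks)
        for i, tr in enumerate(tracks):
            assert np.all(np.abs(tr.centers[0] - truth.centers[0, i]) <= np.array(SP))


class TestNormalization:
    def test_reference_becomes_origin(self):
        a = track_from_centers("a", [[1, 2, 3], [2, 3, 4]])
        b = track_from_centers("b", [[5, 5, 5], [6, 6, 6]])
        out = normalize_to_reference([a, b], "a")
        ref = next(t for t in out if t.cell_id == "a")
        np.testing.assert_allclose(ref.centers, 0.0)

    def test_rigid_translation_cancels(self):
        rng = np.random.default_rng(0)
        offsets = rng.normal(size=(5, 3))
        a = track_from_centers("a", [[1, 2, 3]] * 5 + offsets)
        b = track_from_centers("b", [[4, 4, 4]] * 5 + offsets)
        out = normalize_to_reference([a, b], "a")
        moved = next(t for t in out if t.cell_id == "b")
        np.testing.assert_allclose(moved.centers, [[3, 2, 1]] * 5, atol=1e-12)

    def test_absent_reference_rejected(self):
        a = CellTrack("a", np.zeros((2, 3)), np.array([True, False]))
        with pytest.raises(ValueError, match="absent"):
            normalize_to_reference([a], "a")

    def test_normalization_preserves_distances(self):
        a = track_from_centers("a", [[1, 2, 3], [2, 3, 4]])
        b = track_from_centers("b", [[5, 5, 5], [6, 6, 6]])
        before = distance_series([a, b], ("a", "b")).distances
        after = distance_series(normalize_to_reference([a, b], "a"), ("a", "b")).distances
        np.testing.assert_allclose(before, after)


class TestDistanceSeries:
    def test_static_pair_constant(self):
        a = track_from_centers("a", [[0, 0, 0]] * 4)
        b = track_from_centers("b", [[0, 12, 0]] * 4)
        ds = distance_series([a, b], ("a", "b"))
        np.testing.assert_allclose(ds.distances, 12.0)
        assert ds.delta == 0.0

    def test_scripted_approach_delta(self):
        ys = np.linspace(15.0, 5.0, 10)
        a = track_from_centers("a", [[0, 0, 0]] * 10)
        b = track_from_centers("b", [[0, y, 0] for y in ys])
        ds = distance_series([a, b], ("a", "b"))
        assert ds.delta == pytest.approx(-10.0, abs=0.3)
        assert ds.kendall_tau == pytest.approx(-1.0)

    def test_symmetric_in_pair_order(self):
        a = track_from_centers("a", [[0, 0, 0], [1, 1, 1]])
        b = track_from_centers("b", [[3, 4, 0], [3, 3, 3]])
        d1 = distance_series([a, b], ("a", "b"))
        d2 = distance_series([a, b], ("b", "a"))
        np.testing.assert_allclose(d1.distances, d2.distances)
        assert d1.pair == d2.pair

    def test_too_few_common_frames_rejected(self):
        a = CellTrack("a", np.zeros((3, 3)), np.array([True, False, False]))
        b = CellTrack("b", np.ones((3, 3)), np.array([True, True, True]))
        with pytest.raises(ValueError, match="fewer than 2"):
            distance_series([a, b], ("a", "b"))


class TestHullVolume:
    def test_unit_cube_volume(self):
        corners = [(z, y, x) for z in (0, 1) for y in (0, 1) for x in (0, 1)]
        tracks = [track_from_centers(i, [c]) for i, c in enumerate(corners)]
        metric = hull_volume(tracks, 0)
        assert metric.hull_volume == pytest.approx(1.0)
        assert not metric.degenerate

    def test_collinear_centers_degenerate(self):
        tracks = [track_from_centers(i, [(0, float(i), 0)]) for i in range(5)]
        metric = hull_volume(tracks, 0)
        assert metric.hull_volume == 0.0 and metric.degenerate

    def test_fewer_than_four_points_degenerate(self):
        tracks = [track_from_centers(i, [(0, 0, float(i))]) for i in range(3)]
        assert hull_volume(tracks, 0).degenerate

    def test_invariance_and_scaling(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        base = hull_volume([track_from_centers(i, [p]) for i, p in enumerate(pts)], 0)
        shuffled = hull_volume(
            [track_from_centers(i, [p]) for i, p in enumerate(pts[::-1])], 0
        )
        translated = hull_volume(
            [track_from_centers(i, [p + 7.5]) for i, p in enumerate(pts)], 0
        )
        scaled = hull_volume([track_from_centers(i, [2 * p]) for i, p in enumerate(pts)], 0)
        assert shuffled.hull_volume == pytest.approx(base.hull_volume)
        assert translated.hull_volume == pytest.approx(base.hull_volume)
        assert scaled.hull_volume == pytest.approx(8 * base.hull_volume)

    def test_coalescing_cluster_monotone_decrease(self):
        rng = np.random.default_rng(1)
        start = rng.normal(scale=6.0, size=(6, 3)) + 20.0
        target = np.full(3, 20.0)
        tracks = []
        n_frames = 8
        for i, s in enumerate(start):
            centers = [s + (target - s) * f / (n_frames - 1) for f in range(n_frames)]
            tracks.append(track_from_centers(i, centers))
        volumes = [hull_volume(tracks, f).hull_volume for f in range(n_frames)]
        assert all(v1 > v2 for v1, v2 in zip(volumes[:-1], volumes[1:]))
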