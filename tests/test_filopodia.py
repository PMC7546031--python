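import numpy as np
import pytest

from isletmorph.filopodia import (
    DynamicsParams,
    FilopodiumTrace,
    FilopodiumTrack,
    analyze_movie,
    classify_dynamics,
    classify_length_series,
    link_tracks,
    summarize_dynamics,
    trace_filopodia,
)
from isletmorph.preprocess import preprocess
from isletmorph.segmentation import hysteresis_segment, purify
from isletmorph.synthetic import CellSpec, FilopodiumSpec, NoiseSpec, SceneSpec, render_scene

SP = (1.0, 0.3, 0.3)


def render_cell(fils, grid=(16, 96, 96), center=(8.0, 14.0, 14.0), noise=None, seed=2, n_frames=1):
    fils = [FilopodiumSpec(d, [L] * n_frames) for d, L in fils]
    cell = CellSpec(center=center, semi_axes=(3.0, 3.0, 3.0), filopodia=fils)
    spec = SceneSpec(
        grid_shape=grid, cells=[cell], voxel_spacing=SP, noise=noise, seed=seed, n_frames=n_frames
    )
    return render_scene(spec)


def trace(img, t=0):
    body = purify(hysteresis_segment(img, t=t))
    return trace_filopodia(img, body, frame=t)


class TestEventRules:
    @pytest.mark.parametrize(
        "lengths, expected",
        [
            ([2.0] * 11, (0, True)),
            ([0, 0, 1.5, 1.5, 0, 0, 0, 0, 0, 0, 0], (2, False)),  # appear + disappear
            ([2, 2, 3.2, 3.2, 3.2, 3.2, 3.2, 3.2, 3.2, 3.2, 3.2], (1, False)),  # 1.6x jump
            ([2, 2, 2.9, 2.9, 2.9, 2.9, 2.9, 2.9, 2.9, 2.9, 2.9], (0, True)),  # 45 % only
            ([0.5] * 11, (0, False)),  # never reaches min length
        ],
    )
    def test_classification_examples(self, lengths, expected):
        assert classify_length_series(lengths, DynamicsParams()) == expected

    def test_min_length_crossing_counts_once(self):
        # 0.8 -> 2.0 crosses min_length: one appearance, not also a length change
        events, _ = classify_length_series([0.8, 2.0, 2.0], DynamicsParams())
        assert events == 1

    def test_window_longer_than_series_rejected(self):
        track = FilopodiumTrack(track_id=0)
        track.add(FilopodiumTrace(0, np.array([[0, 0, 0], [0, 2, 0.0]]), np.zeros(3)))
        with pytest.raises(ValueError, match="window"):
            classify_dynamics(track, DynamicsParams(), n_frames=5)


class TestTracing:
    def test_single_filopodium_single_trace_within_15pct(self):
        img, _ = render_cell([((0, 1, 0), 6.0)])
        traces = trace(img)
        assert len(traces) == 1
        assert traces[0].length == pytest.approx(6.0, rel=0.15)

    def test_sphere_without_filopodia_yields_empty(self):
        img, _ = render_cell([], noise=NoiseSpec())
        img = preprocess(img, median_radius=1, bg_radius=0.0)
        assert trace(img) == []

    def test_three_filopodia_rank_ordered(self):
        img, _ = render_cell(
            [((0, 1, 0), 2.0), ((0, 0, 1), 5.0), ((0, -1, 0), 9.0)],
            grid=(20, 110, 110),
            center=(10.0, 16.5, 16.5),
            noise=NoiseSpec(),
        )
        img = preprocess(img, median_radius=1, bg_radius=0.0)
        traces = trace(img)
        assert len(traces) == 3
        by_len = sorted(tr.length for tr in traces)
        # ranks must match 2 < 5 < 9 with separations preserved
        assert by_len[0] < by_len[1] < by_len[2]
        assert by_len[2] == pytest.approx(9.0, rel=0.2)
        assert by_len[1] == pytest.approx(5.0, rel=0.2)

    def test_trace_path_invariants(self):
        img, _ = render_cell([((0, 1, 0), 6.0)])
        tr = trace(img)[0]
        assert tr.path.shape[0] >= 2
        assert tr.length >= 0
        np.testing.assert_allclose(tr.base_point, tr.path[0])

    def test_min_length_monotonicity(self):
        # raising min_length never increases the number of filopodia retained
        img, _ = render_cell(
            [((0, 1, 0), 2.0), ((0, -1, 0), 6.0)],
            grid=(16, 100, 100),
            center=(8.0, 15.0, 15.0),
        )
        traces = trace(img)
        counts = []
        for min_len in (1.0, 3.0, 5.0):
            counts.append(sum(1 for t in traces if t.length >= min_len))
        assert counts == sorted(counts, reverse=True)


class TestLinking:
    def _trace_at(self, frame, base, length=3.0):
        base = np.asarray(base, float)
        path = np.array([base, base + [0, length, 0]])
        return FilopodiumTrace(frame, path, base)

    def test_persistent_filopodium_one_track(self):
        frames = {t: [self._trace_at(t, (5.0, 5.0, 5.0))] for t in range(11)}
        tracks = link_tracks(frames)
        assert len(tracks) == 1
        assert len(tracks[0].traces) == 11

    def test_distant_bases_never_swap(self):
        frames = {
            t: [self._trace_at(t, (5.0, 5.0, 5.0), 3.0), self._trace_at(t, (5.0, 15.0, 5.0), 6.0)]
            for t in range(5)
        }
        tracks = link_tracks(frames)
        assert len(tracks) == 2
        for track in tracks:
            lengths = [tr.length for tr in track.traces.values()]
            assert np.ptp(lengths) == 0  # no identity swap

    def test_appearance_opens_new_track(self):
        frames = {t: [self._trace_at(t, (5.0, 5.0, 5.0))] for t in range(11)}
        for t in range(5, 11):
            frames[t].append(self._trace_at(t, (5.0, 12.0, 5.0), 2.0))
        tracks = link_tracks(frames)
        assert len(tracks) == 2
        new = [tr for tr in tracks if min(tr.traces) == 5]
        assert len(new) == 1


class TestMovieRecovery:
    def test_scripted_movie_recovers_truth_labels(self):
        from isletmorph.synthetic import make_dynamics_cohort

        spec, img, truth = make_dynamics_cohort(n_cells=1, seed=11)[0]
        tracks = analyze_movie(img)
        meas = sorted((t.dynamic_events, bool(t.stable)) for t in tracks)
        true = sorted((int(e), bool(s)) for e, s in truth.event_labels.values())
        assert meas == true


class TestSummaries:
    def _stable_track(self, tid):
        track = FilopodiumTrack(track_id=tid)
        for t in range(11):
            base = np.array([5.0, 5.0, 5.0])
            track.add(FilopodiumTrace(t, np.array([base, base + [0, 3, 0]]), base))
        return track

    def _dynamic_track(self, tid):
        track = FilopodiumTrack(track_id=tid)
        for t in range(5):
            base = np.array([5.0, 9.0, 5.0])
            track.add(FilopodiumTrace(t, np.array([base, base + [0, 2, 0]]), base))
        return track  # disappears at frame 5 -> one event

    def test_counts_and_group_comparison(self):
        cells = {}
        groups = {}
        for i in range(4):
            cells[f"iso{i}"] = [self._stable_track(0), self._dynamic_track(1)]
            groups[f"iso{i}"] = "isolated"
            cells[f"clus{i}"] = [self._stable_track(0), self._stable_track(1)]
            groups[f"clus{i}"] = "clustered"
        df, comparisons = summarize_dynamics(cells, groups)
        iso = df[df.group == "isolated"]
        assert (iso.dynamic_events == 1).all()
        assert (iso.stable_filopodia == 1).all()
        assert comparisons["stable_filopodia"]["p"] < 0.05

    def test_empty_track_list_counts_zero(self):
        df, _ = summarize_dynamics({"c": []}, {"c": "isolated"})
        assert df.loc[0, "dynamic_events"] == 0
        assert df.loc[0, "stable_filopodia"] == 0

    def test_identical_cohorts_null(self):
        cells = {"a": [self._stable_track(0)], "b": [self._stable_track(0)],
                 "c": [self._stable_track(0)], "d": [self._stable_track(0)]}
        groups = {"a": "isolated", "b": "isolated", "c": "clustered", "d": "clustered"}
        _, comparisons = summarize_dynamics(cells, groups)
        assert comparisons["stable_filopodia"]["p"] == pytest.approx(1.0)
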