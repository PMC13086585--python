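"""FA dynamics tests: drift, cropping, linking, kinetics, novel counting."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fa_screenkit import dynamics as dyn
from fa_screenkit import synthetic
from fa_screenkit.datatypes import (END_DEATH, END_INTO_MERGE,
                                    END_LAST_FRAME, ORIGIN_BIRTH,
                                    ORIGIN_FIRST_FRAME, ORIGIN_FROM_SPLIT,
                                    DynamicsParams, FATrack, Movie)
from fa_screenkit.synthetic import FAEventSpec, SynthMovieSpec


def _event(birth, death, center, **kw):
    kw.setdefault("assembly_rate", 0.0)
    kw.setdefault("disassembly_rate", 0.0)
    kw.setdefault("peak_frame", birth)
    return FAEventSpec(birth_frame=birth, death_frame=death, center=center,
                       **kw)


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def test_planted_drift_recovered_exactly():
    events = [_event(0, 14, (40, 40), axes=(6, 4)),
              _event(0, 14, (70, 55), axes=(5, 3), peak_intensity=1500.0)]
    steps = [(0, 0)] + [(3, -2)] * 14
    movie, truth = synthetic.make_movie(SynthMovieSpec(
        image_shape=(200, 200), n_frames=15, events=events,
        drift_path=steps, seed=1))
    corrected, offsets = dyn.correct_drift(movie)
    assert offsets == truth.drift_cumulative
    # corrected content is static: frames equal where not zero-padded
    f0 = corrected.frames[0]
    for f in range(1, 15):
        inner = corrected.frames[f] > 0
        np.testing.assert_array_equal(corrected.frames[f][inner],
                                      f0[inner])


def test_static_movie_zero_offsets():
    movie, _ = synthetic.make_movie(SynthMovieSpec(
        image_shape=(100, 100), n_frames=5,
        events=[_event(0, 4, (50, 50), axes=(6, 4))], seed=0))
    _, offsets = dyn.correct_drift(movie)
    assert offsets == [(0, 0)] * 5


def test_drift_step_clamped_to_max_shift():
    movie, _ = synthetic.make_movie(SynthMovieSpec(
        image_shape=(200, 200), n_frames=2,
        events=[_event(0, 1, (100, 100), axes=(6, 4))],
        drift_path=[(0, 0), (30, 0)], seed=0))
    _, offsets = dyn.correct_drift(movie)
    assert offsets == [(0, 0), (20, 0)]


def test_drift_empty_frame_warns_zero_step():
    frames = np.full((3, 64, 64), 5.0)
    frames[0, 20:30, 20:30] = 500.0
    frames[2, 22:32, 20:30] = 500.0
    with pytest.warns(UserWarning, match="drift_min_grey"):
        _, offsets = dyn.correct_drift(Movie(frames=frames))
    assert offsets[1] == (0, 0)


def test_drift_then_tracking_matches_undrifted():
    # bounded drift keeps the correction's zero padding outside the crop box
    ev = [_event(0, 25, (80, 70), axes=(7, 5)),
          _event(5, 20, (50, 100), axes=(6, 4))]
    still, _ = synthetic.make_movie(SynthMovieSpec(
        image_shape=(200, 200), n_frames=30, events=ev, seed=2))
    drifted, _ = synthetic.make_movie(SynthMovieSpec(
        image_shape=(200, 200), n_frames=30, events=ev,
        drift_path=[(0, 0)] + [(1, 2)] * 8 + [(0, 0)] * 21, seed=2))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)  # empty tail frames
        corrected, _ = dyn.correct_drift(drifted)
    # the paper's pipeline crops the black padding left by the correction
    # before tracking
    t_still = dyn.track_fas(dyn.autocrop(still))
    t_corr = dyn.track_fas(dyn.autocrop(corrected))
    key = sorted((tr.start_frame, tr.end_frame) for tr in t_still)
    assert sorted((tr.start_frame, tr.end_frame) for tr in t_corr) == key


# ---------------------------------------------------------------------------
# autocrop
# ---------------------------------------------------------------------------

def test_autocrop_bounds_blurred_footprint():
    frames = np.full((3, 200, 260), 5.0)
    frames[:, 10:50, 15:55] = 3000.0  # cell in a corner
    cropped = dyn.autocrop(Movie(frames=frames))
    # box within the footprint dilated by the blur support (~2.5 sigma)
    assert cropped.frames.shape[1] <= 40 + 2 * 40
    assert cropped.frames.shape[2] <= 40 + 2 * 40
    assert cropped.frames.max() == 3000.0


def test_autocrop_full_frame_cell():
    # a cell filling the whole frame: degenerate blurred projection, movie
    # returned uncropped
    frames = np.full((2, 64, 64), 2500.0)
    with pytest.warns(UserWarning):
        cropped = dyn.autocrop(Movie(frames=frames))
    assert cropped.frames.shape == (2, 64, 64)


def test_autocrop_keeps_largest_component():
    frames = np.full((2, 220, 220), 5.0)
    frames[:, 130:210, 130:210] = 3000.0  # large
    frames[:, 15:23, 15:23] = 3000.0  # 10x smaller
    cropped = dyn.autocrop(Movie(frames=frames))
    assert cropped.frames.shape[1] < 160
    assert cropped.frames.max() == 3000.0
    assert cropped.frames[0, 0, 0] != 3000.0  # small blob not in the box


def test_autocrop_empty_mask_uncropped():
    frames = np.full((2, 64, 64), 7.0)
    with pytest.warns(UserWarning):
        cropped = dyn.autocrop(Movie(frames=frames))
    assert cropped.frames.shape == (2, 64, 64)


# ---------------------------------------------------------------------------
# segmentation and tracking
# ---------------------------------------------------------------------------

def test_min_fa_size_boundary():
    params = DynamicsParams()
    frame = np.zeros((64, 64))
    frame[10:12, 10:14] = 3000.0  # 8 px: below the 10-px minimum
    frame[40:42, 40:45] = 3000.0  # 10 px: kept
    labels = dyn.segment_frame(frame, params)
    kept = np.unique(labels)[1:]
    assert len(kept) == 1
    assert (labels[40:42, 40:45] > 0).all()


def test_single_object_single_track():
    movie, _ = synthetic.make_movie(SynthMovieSpec(
        image_shape=(128, 128), n_frames=61,
        events=[_event(10, 60, (60, 60), axes=(7, 5))], seed=0))
    tracks = dyn.track_fas(movie)
    assert len(tracks) == 1
    tr = tracks[0]
    assert tr.origin == ORIGIN_BIRTH
    assert (tr.start_frame, tr.end_frame) == (10, 60)
    assert tr.end == END_LAST_FRAME


def _stack_from_rects(n_frames, shape, rects_per_frame):
    """Build a label stack from per-frame lists of (r0, c0, h, w, label)."""
    stack = []
    for f in range(n_frames):
        lab = np.zeros(shape, dtype=np.int32)
        for r0, c0, h, w, label in rects_per_frame.get(f, []):
            lab[r0:r0 + h, c0:c0 + w] = label
        stack.append(lab)
    return stack


def test_link_merge_hand_enumerated():
    # two objects approach and fuse at frame 2; larger parent survives
    shape = (40, 60)
    rects = {
        0: [(10, 5, 4, 8, 1), (10, 28, 3, 6, 2)],
        1: [(10, 9, 4, 8, 1), (10, 24, 3, 6, 2)],
        2: [(10, 13, 4, 18, 1)],  # fused component overlapping both
        3: [(10, 13, 4, 18, 1)],
    }
    tracks = dyn.link_label_stack(_stack_from_rects(4, shape, rects))
    assert len(tracks) == 2
    big = next(t for t in tracks if t.areas[0] == 32)
    small = next(t for t in tracks if t.areas[0] == 18)
    assert big.end == END_LAST_FRAME
    assert (big.start_frame, big.end_frame) == (0, 3)
    assert small.end == END_INTO_MERGE
    assert small.end_frame == 1


def test_link_split_hand_enumerated():
    # one object splits at frame 1: parent keeps the larger fragment,
    # the smaller fragment starts a from_split track
    shape = (40, 60)
    rects = {
        0: [(10, 10, 4, 10, 1)],
        1: [(10, 10, 4, 6, 1), (10, 18, 4, 2, 2)],
        2: [(10, 10, 4, 6, 1), (10, 18, 4, 2, 2)],
    }
    tracks = dyn.link_label_stack(_stack_from_rects(3, shape, rects))
    assert len(tracks) == 2
    parent = next(t for t in tracks if t.start_frame == 0)
    frag = next(t for t in tracks if t.start_frame == 1)
    assert parent.areas == [40, 24, 24]
    assert frag.origin == ORIGIN_FROM_SPLIT
    assert frag.areas == [8, 8]


def test_track_fas_merge_movie():
    e1 = FAEventSpec(birth_frame=0, death_frame=39, center=(50, 40),
                     axes=(6, 5), assembly_rate=0, disassembly_rate=0,
                     peak_frame=0, peak_intensity=2000.0,
                     growth_px_per_frame=0.2)
    e2 = FAEventSpec(birth_frame=0, death_frame=39, center=(50, 64),
                     axes=(5, 4), assembly_rate=0, disassembly_rate=0,
                     peak_frame=0, peak_intensity=1500.0,
                     growth_px_per_frame=0.2)
    movie, truth = synthetic.make_movie(SynthMovieSpec(
        image_shape=(100, 100), n_frames=40, events=[e1, e2],
        merge_pairs=((0, 1),), seed=0))
    assert (0, 1) in truth.merge_frames
    tracks = dyn.track_fas(movie)
    assert len(tracks) == 2
    ends = sorted(t.end for t in tracks)
    assert ends == [END_INTO_MERGE, END_LAST_FRAME]
    merged_away = next(t for t in tracks if t.end == END_INTO_MERGE)
    assert merged_away.end_frame <= truth.merge_frames[(0, 1)]


def test_speck_below_min_size_not_tracked():
    frames = np.full((5, 64, 64), 10.0)
    frames[:, 20:22, 20:24] = 3000.0  # 8 px
    tracks = dyn.track_fas(Movie(frames=frames))
    assert tracks == []


# ---------------------------------------------------------------------------
# rate fitting
# ---------------------------------------------------------------------------

def _track_from_intensities(intensities, start=0):
    n = len(intensities)
    return FATrack(track_id=1, start_frame=start, areas=[20] * n,
                   intensities=list(intensities),
                   centroids=[(0.0, 0.0)] * n)


def test_fit_rates_planted_exponential():
    t = np.arange(30) * 2.0
    up = 100.0 * np.exp(0.05 * t)
    down = up[-1] * np.exp(-0.03 * (np.arange(1, 30) * 2.0))
    track = _track_from_intensities(np.concatenate([up, down]))
    a, d = dyn.fit_rates(track, 2.0)
    assert a == pytest.approx(0.05, abs=5e-4)
    assert d == pytest.approx(0.03, abs=5e-4)


def test_fit_rates_constant_track_zero():
    track = _track_from_intensities([500.0] * 30)
    a, d = dyn.fit_rates(track, 2.0)
    assert a == pytest.approx(0.0, abs=1e-12)
    assert d == pytest.approx(0.0, abs=1e-12)


def test_fit_rates_short_track_none():
    track = _track_from_intensities([100, 120, 140, 160, 150, 130])
    assert dyn.fit_rates(track, 2.0) == (None, None)


def test_fit_rates_nonpositive_intensity_error():
    track = _track_from_intensities([100.0] * 10 + [0.0] + [100.0] * 10)
    with pytest.raises(ValueError, match="log"):
        dyn.fit_rates(track, 2.0)


def test_rate_recovery_under_noise_snr10():
    # planted exponential kinetics, SNR >= 10 at the weakest phase point
    ev = FAEventSpec(birth_frame=0, death_frame=59, center=(60, 60),
                     axes=(9, 6), peak_intensity=3000.0,
                     assembly_rate=0.05, disassembly_rate=0.03,
                     peak_frame=30)
    for seed in range(5):
        movie, _ = synthetic.make_movie(SynthMovieSpec(
            image_shape=(128, 128), n_frames=60, events=[ev],
            noise_sd=30.0, seed=seed))
        tracks = dyn.track_fas(movie)
        main = max(tracks, key=lambda t: t.n_frames)
        a, d = dyn.fit_rates(main, 2.0)
        assert abs(a - 0.05) / 0.05 < 0.05
        assert abs(d - 0.03) / 0.03 < 0.05


# ---------------------------------------------------------------------------
# novel-FA counting
# ---------------------------------------------------------------------------

def _mk_track(tid, origin):
    return FATrack(track_id=tid, start_frame=0, areas=[20], intensities=[1.0],
                   centroids=[(0.0, 0.0)], origin=origin)


def test_count_novel_filters_origins():
    tracks = [_mk_track(1, ORIGIN_FIRST_FRAME), _mk_track(2, ORIGIN_FIRST_FRAME),
              _mk_track(3, ORIGIN_FROM_SPLIT), _mk_track(4, ORIGIN_BIRTH),
              _mk_track(5, ORIGIN_BIRTH)]
    per_frame, total = dyn.count_novel_fas(tracks, 10)
    assert total == 2
    assert per_frame == pytest.approx(0.2)


def test_count_novel_all_first_frame_zero():
    tracks = [_mk_track(i, ORIGIN_FIRST_FRAME) for i in range(4)]
    assert dyn.count_novel_fas(tracks, 5)[1] == 0


def test_count_novel_scheduled_births_recovered():
    events = [_event(5 + 9 * i, 110, (20 + 17 * (i % 6), 20 + 30 * (i // 6)),
                     axes=(5, 3), peak_intensity=2500.0)
              for i in range(12)]
    movie, _ = synthetic.make_movie(SynthMovieSpec(
        image_shape=(128, 128), n_frames=120, events=events, seed=0))
    tracks = dyn.track_fas(movie)
    per_frame, total = dyn.count_novel_fas(tracks, 120)
    assert total == 12
    assert per_frame == pytest.approx(0.1)


@given(st.permutations(list(range(1, 8))))
@settings(max_examples=25, deadline=None)
def test_count_novel_relabel_invariance(perm):
    origins = [ORIGIN_BIRTH, ORIGIN_FIRST_FRAME, ORIGIN_BIRTH,
               ORIGIN_FROM_SPLIT, ORIGIN_BIRTH, ORIGIN_FIRST_FRAME,
               ORIGIN_BIRTH]
    tracks = [_mk_track(tid, o) for tid, o in zip(perm, origins)]
    assert dyn.count_novel_fas(tracks, 10)[1] == 4


def test_tracks_disjoint_pixels_per_frame():
    # every foreground pixel belongs to at most one track per frame: the
    # label stacks are partitions by construction; verify via track areas
    movie, _ = synthetic.make_movie(SynthMovieSpec(
        image_shape=(128, 128), n_frames=20, first_frame_fas=6, seed=4))
    params = DynamicsParams()
    frames = np.asarray(movie.frames, dtype=float)
    stacks = [dyn.segment_frame(frames[f], params) for f in range(20)]
    tracks = dyn.link_label_stack(stacks, intensity_stack=frames)
    for f in range(20):
        total_fg = int((stacks[f] > 0).sum())
        tracked = sum(tr.areas[f - tr.start_frame] for tr in tracks
                      if tr.start_frame <= f <= tr.end_frame)
        assert tracked == total_fg


def test_summarize_dynamics():
    movie, _ = synthetic.make_movie(SynthMovieSpec(
        image_shape=(128, 128), n_frames=61,
        events=[FAEventSpec(birth_frame=0, death_frame=60, center=(60, 60),
                            axes=(9, 6), peak_intensity=3000.0,
                            assembly_rate=0.05, disassembly_rate=0.03,
                            peak_frame=30)], seed=0))
    tracks = dyn.track_fas(movie)
    summary = dyn.summarize_dynamics(tracks, 61, 2.0)
    assert summary.n_tracks == 1
    assert summary.novel_fas_total == 0  # first-frame track filtered
    assert summary.assembly_rate == pytest.approx(0.05, rel=0.05)
    assert summary.disassembly_rate == pytest.approx(0.03, rel=0.05)
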