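"""Linking, track filters, duration and migration speed."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adhesiondyn.detect import Puncta
from adhesiondyn.simulate import SimConfig, simulate_timelapse
from adhesiondyn.track import (
    TOO_SHORT,
    TOUCHES_FIRST,
    TOUCHES_LAST,
    CellTrajectory,
    cell_speed,
    duration,
    filter_tracks,
    link_tracks,
    measure_cell_trajectory,
)
from conftest import span_track


def det(frame, row, col, mfi=50.0):
    return Puncta(
        frame_index=frame,
        centroid=(float(row), float(col)),
        pixels=np.array([[int(round(row)), int(round(col))]]),
        area_px=4,
        mfi=mfi,
    )


class TestLinking:
    def test_stationary_spot_single_track(self):
        frames = [[det(f, 10, 10)] for f in range(10)]
        tracks = link_tracks(frames)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 10

    def test_identities_preserved_over_swap_tempting_step(self):
        """Two nearby spots each move slightly; the assignment must pick the
        minimum-total-displacement matching (oracle: enumerate both)."""
        a0, b0 = (10.0, 10.0), (10.0, 16.0)
        a1, b1 = (10.0, 12.0), (10.0, 18.0)
        frames = [[det(0, *a0), det(0, *b0)], [det(1, *a1), det(1, *b1)]]
        # brute-force oracle over the two one-to-one assignments
        direct = np.hypot(*(np.array(a1) - a0)) + np.hypot(*(np.array(b1) - b0))
        swapped = np.hypot(*(np.array(b1) - a0)) + np.hypot(*(np.array(a1) - b0))
        assert direct < swapped
        tracks = link_tracks(frames, max_disp_px=5.0)
        assert len(tracks) == 2
        for t in tracks:
            start, end = t.punctae[0].centroid, t.punctae[-1].centroid
            assert (start, end) in [(a0, a1), (b0, b1)]

    def test_no_gap_closing(self):
        frames = [[det(0, 10, 10)], [det(1, 10, 10)], [], [det(3, 10, 10)]]
        tracks = link_tracks(frames)
        assert sorted(t.n_frames for t in tracks) == [1, 2]

    def test_zero_detections_zero_tracks(self):
        assert link_tracks([[], [], []]) == []

    def test_detections_conserved(self):
        rng = np.random.default_rng(0)
        frames = [
            [det(f, rng.uniform(0, 50), rng.uniform(0, 50)) for _ in range(rng.integers(0, 6))]
            for f in range(15)
        ]
        tracks = link_tracks(frames, max_disp_px=8.0)
        n_linked = sum(t.n_frames for t in tracks)
        assert n_linked == sum(len(f) for f in frames)


class TestFilter:
    def test_enumerated_fixture_matches_rule_oracle(self):
        """Ten constructed tracks; survivors enumerated by applying the
        stated rules by hand (length >= 9, interior start and end)."""
        n_total = 30
        spans = [
            (0, 21), (5, 8), (5, 9), (22, 8), (1, 29),
            (1, 9), (10, 18), (3, 8), (0, 30), (15, 10),
        ]
        tracks = [span_track(s, l, track_id=i) for i, (s, l) in enumerate(spans)]
        # independent oracle: brute-force the stated rules
        expected_kept = {
            i for i, (s, l) in enumerate(spans)
            if s != 0 and (s + l - 1) != n_total - 1 and l >= 9
        }
        assert expected_kept == {2, 5, 6, 9}
        kept, removed = filter_tracks(tracks, n_total)
        assert {t.track_id for t in kept} == expected_kept
        assert {t.track_id for t in removed} == set(range(10)) - expected_kept

    def test_exactly_8_frames_removed_9_kept(self):
        kept, removed = filter_tracks(
            [span_track(5, 8, 0), span_track(5, 9, 1)], n_frames_total=40
        )
        assert [t.track_id for t in kept] == [1]
        assert TOO_SHORT in removed[0].qc_flags

    def test_first_and_last_frame_touchers_removed(self):
        kept, removed = filter_tracks(
            [span_track(0, 21, 0), span_track(25, 15, 1)], n_frames_total=40
        )
        assert kept == []
        assert TOUCHES_FIRST in removed[0].qc_flags
        assert TOUCHES_LAST in removed[1].qc_flags

    @settings(derandomize=True, max_examples=50)
    @given(
        spans=st.lists(
            st.tuples(st.integers(0, 30), st.integers(1, 25)), min_size=1, max_size=15
        )
    )
    def test_idempotent_and_partitions(self, spans):
        tracks = [span_track(s, l, track_id=i) for i, (s, l) in enumerate(spans)]
        kept, removed = filter_tracks(tracks, n_frames_total=60)
        assert len(kept) + len(removed) == len(tracks)
        kept2, removed2 = filter_tracks(kept, n_frames_total=60)
        assert removed2 == [] and len(kept2) == len(kept)


class TestDuration:
    def test_frame_count(self):
        assert duration(span_track(3, 10)) == 10

    def test_minimal_kept_track_is_9(self):
        kept, _ = filter_tracks([span_track(4, 9)], n_frames_total=30)
        assert duration(kept[0]) == 9

    def test_mean_duration_recovered_from_stack(self, small_stack):
        """Mean measured track duration within 10% of the ground-truth mean
        occupancy of detectable frames."""
        from adhesiondyn.detect import detect_stack
        cfg, stack, truth = small_stack
        dets = detect_stack(stack.channel(0))
        tracks = link_tracks(dets)
        # ground-truth occupancy: frames with true amplitude above the
        # detector's effective floor
        occ = (
            truth.positions[truth.positions.true_intensity >= 60.0]
            .groupby("object_id")
            .size()
        )
        long_tracks = [t for t in tracks if t.n_frames >= 5]
        measured = np.mean([duration(t) for t in long_tracks])
        assert measured == pytest.approx(occ.mean(), rel=0.10)


class TestCellSpeed:
    def test_stationary_cell_zero(self):
        traj = CellTrajectory(np.tile([5.0, 5.0], (10, 1)), 0.75, 0.1)
        assert cell_speed(traj) == 0.0

    def test_hand_arithmetic(self):
        # 1 px/frame at 0.1 µm/px and 0.75 s/frame -> 0.1333... µm/s
        cent = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        traj = CellTrajectory(cent, 0.75, 0.1)
        assert cell_speed(traj) == pytest.approx(0.1 / 0.75)

    def test_flagged_frames_excluded_pairwise(self):
        cent = np.column_stack([np.arange(6.0), np.zeros(6)])
        cent[3] = np.nan
        traj = CellTrajectory(cent, 1.0, 1.0)
        assert cell_speed(traj) == pytest.approx(1.0)

    def test_too_few_valid_frames_rejected(self):
        with pytest.raises(ValueError):
            CellTrajectory(np.array([[1.0, 1.0]]), 1.0, 1.0)

    def test_recovers_simulated_speed(self):
        cfg = SimConfig(
            n_punctae=0, n_frames=60, image_shape=(96, 96), cell_speed_um_s=0.05,
            noise_sd=10.0, rng_seed=2,
        )
        stack, _ = simulate_timelapse(cfg)
        traj = measure_cell_trajectory(
            stack.channel(0), cfg.frame_interval_s, cfg.pixel_size_um
        )
        assert cell_speed(traj) == pytest.approx(0.05, rel=0.15)
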