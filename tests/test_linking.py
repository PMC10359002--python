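"""Data association, track building, and fragment merging."""

import itertools
import math

import numpy as np
import pytest

from mosquitrack import (
    Detection,
    FrameDetections,
    LinkParams,
    SceneSpec,
    Track,
    apply_observation_model,
    associate_frame,
    build_tracks,
    direction_consistency,
    generate_scene,
    merge_track_fragments,
)
from mosquitrack.linking import assignment_cost

from conftest import straight_track


def one_point_track(track_id, x, y, frame=1):
    return Track(
        track_id=track_id, frames=np.array([frame]), x=np.array([x]), y=np.array([y])
    )


def brute_force_min_cost(track_pos, det_pos, gating):
    """Independent oracle: enumerate all injective partial assignments.

    Maximises the number of within-gate matches, then minimises the total
    Euclidean distance. Returns (best size, best cost).
    """
    n_t, n_d = len(track_pos), len(det_pos)
    admissible = {
        (i, j): math.dist(track_pos[i], det_pos[j])
        for i in range(n_t)
        for j in range(n_d)
        if math.dist(track_pos[i], det_pos[j]) <= gating
    }
    best_size, best_cost = 0, 0.0
    for size in range(min(n_t, n_d), -1, -1):
        found = False
        cost_min = math.inf
        for tsub in itertools.combinations(range(n_t), size):
            for dperm in itertools.permutations(range(n_d), size):
                pairs = list(zip(tsub, dperm))
                if all(p in admissible for p in pairs):
                    found = True
                    cost_min = min(cost_min, sum(admissible[p] for p in pairs))
        if found:
            best_size, best_cost = size, cost_min
            break
    return best_size, best_cost


class TestAssociateFrame:
    def test_well_separated_pairs_match_nearest(self):
        tracks = [one_point_track(1, 10, 10), one_point_track(2, 100, 100)]
        dets = FrameDetections(
            frame=2,
            detections=[Detection(2, 12, 11), Detection(2, 98, 103)],
        )
        a = associate_frame(tracks, dets, LinkParams())
        assert a.matches == [(1, 0), (2, 1)]
        assert a.unmatched_tracks == [] and a.unmatched_detections == []

    def test_detection_beyond_gate_left_unmatched(self):
        tracks = [one_point_track(1, 10, 10)]
        dets = FrameDetections(frame=2, detections=[Detection(2, 200, 200)])
        a = associate_frame(tracks, dets, LinkParams(gating_radius_px=50))
        assert a.matches == []
        assert a.unmatched_tracks == [1] and a.unmatched_detections == [0]

    def test_empty_inputs_give_empty_assignment(self):
        a = associate_frame([], FrameDetections(frame=1, detections=[]), LinkParams())
        assert a.matches == []

    @pytest.mark.parametrize("trial", range(60))
    def test_cost_equals_bruteforce_minimum(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_t = int(rng.integers(1, 7))
        n_d = int(rng.integers(1, 7))
        gating = float(rng.uniform(20, 60))
        track_pos = rng.uniform(0, 100, size=(n_t, 2))
        det_pos = rng.uniform(0, 100, size=(n_d, 2))
        tracks = [
            one_point_track(i + 1, float(p[0]), float(p[1])) for i, p in enumerate(track_pos)
        ]
        dets = FrameDetections(
            frame=2,
            detections=[Detection(2, float(p[0]), float(p[1])) for p in det_pos],
        )
        params = LinkParams(gating_radius_px=gating)
        a = associate_frame(tracks, dets, params)
        size, cost = brute_force_min_cost(track_pos, det_pos, gating)
        assert len(a.matches) == size
        assert assignment_cost(tracks, dets, a, params) == pytest.approx(cost)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        tracks = [
            one_point_track(i + 1, *rng.uniform(0, 50, 2)) for i in range(4)
        ]
        dets = FrameDetections(
            frame=2,
            detections=[Detection(2, *rng.uniform(0, 50, 2)) for _ in range(4)],
        )
        a1 = associate_frame(tracks, dets, LinkParams())
        a2 = associate_frame(tracks, dets, LinkParams())
        assert a1.matches == a2.matches

    def test_exact_tie_breaks_lexicographically(self):
        # two tracks at the same point, two detections at the same point:
        # all four costs equal; expect (1,0),(2,1)
        tracks = [one_point_track(1, 10, 10), one_point_track(2, 10, 10)]
        dets = FrameDetections(
            frame=2,
            detections=[Detection(2, 12, 10), Detection(2, 12, 10.0000001)],
        )
        a = associate_frame(tracks, dets, LinkParams())
        assert a.matches == [(1, 0), (2, 1)]


class TestDirectionConsistency:
    def test_single_point_track_always_passes(self):
        t = one_point_track(1, 10, 10)
        assert direction_consistency(t, Detection(2, 500, 500), LinkParams())

    def test_full_reversal_fails(self):
        t = straight_track(n=5, vx=5.0, vy=0.0)  # due +x at 5 px/frame
        behind = Detection(6, float(t.x[-1]) - 5.0, float(t.y[-1]))
        assert not direction_consistency(t, behind, LinkParams(max_turn_deg=120))

    def test_thirty_degree_turn_passes(self):
        t = straight_track(n=5, vx=5.0, vy=0.0)
        step = 5.0
        cand = Detection(
            6,
            float(t.x[-1]) + step * math.cos(math.radians(30)),
            float(t.y[-1]) + step * math.sin(math.radians(30)),
        )
        # oracle: angle via dot product of unit vectors
        v1 = np.array([1.0, 0.0])
        v2 = np.array([math.cos(math.radians(30)), math.sin(math.radians(30))])
        angle = math.degrees(math.acos(float(np.dot(v1, v2))))
        assert angle == pytest.approx(30.0)
        assert direction_consistency(t, cand, LinkParams(max_turn_deg=120))

    def test_resting_track_exempt_from_direction_gate(self):
        # jittering sub-pixel track: heading undefined, any candidate passes
        rng = np.random.default_rng(2)
        frames = np.arange(1, 8)
        t = Track(
            track_id=1,
            frames=frames,
            x=100 + rng.normal(0, 0.3, 7),
            y=100 + rng.normal(0, 0.3, 7),
        )
        cand = Detection(8, 99.5, 100.5)
        assert direction_consistency(t, cand, LinkParams())


class TestBuildTracks:
    def test_repeated_stationary_detection_gives_one_track(self):
        frames = [
            FrameDetections(frame=f, detections=[Detection(f, 50.0, 60.0)])
            for f in range(1, 101)
        ]
        tracks = build_tracks(frames)
        assert len(tracks) == 1
        assert len(tracks[0]) == 100

    def test_exact_recovery_on_clean_scene(self):
        scene = generate_scene(
            SceneSpec(seed=1, n_flying=2, n_resting=3, noise_sigma_px=0.0)
        )
        dets, _ = apply_observation_model(scene)
        tracks = build_tracks(dets)
        assert len(tracks) == 5
        for est, true in zip(tracks, scene.true_tracks):
            assert np.array_equal(est.frames, true.frames)
            assert np.array_equal(est.x, true.x)
            assert np.array_equal(est.y, true.y)

    def test_short_gap_coasts_into_single_track_with_hole(self):
        frames = []
        for f in range(1, 21):
            if 8 <= f <= 10:  # 3-frame detection gap
                frames.append(FrameDetections(frame=f, detections=[]))
            else:
                frames.append(
                    FrameDetections(frame=f, detections=[Detection(f, 10.0 + f, 20.0)])
                )
        tracks = build_tracks(frames, LinkParams(max_coast_frames=5))
        assert len(tracks) == 1
        assert set([8, 9, 10]).isdisjoint(tracks[0].frames.tolist())
        assert len(tracks[0]) == 17

    def test_gap_longer_than_coast_fragments_track(self):
        frames = []
        for f in range(1, 31):
            if 10 <= f <= 20:
                frames.append(FrameDetections(frame=f, detections=[]))
            else:
                frames.append(
                    FrameDetections(frame=f, detections=[Detection(f, 10.0, 20.0)])
                )
        tracks = build_tracks(frames, LinkParams(max_coast_frames=5))
        assert len(tracks) == 2

    def test_detection_conservation(self, noisy_cluttered_scene):
        dets, _ = apply_observation_model(noisy_cluttered_scene)
        n_in = sum(len(fd) for fd in dets)
        tracks = build_tracks(dets)
        n_out = sum(int(t.detected_mask().sum()) for t in tracks)
        assert n_out == n_in

    def test_determinism(self, noisy_cluttered_scene):
        dets, _ = apply_observation_model(noisy_cluttered_scene)
        t1 = build_tracks(dets)
        t2 = build_tracks(dets)
        assert len(t1) == len(t2)
        for a, b in zip(t1, t2):
            assert a.track_id == b.track_id
            assert np.array_equal(a.frames, b.frames)
            assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


class TestMergeFragments:
    def test_joinable_fragments_merge_keeping_earlier_id(self):
        a = straight_track(track_id=1, n=50, frames=np.arange(1, 51))
        b = straight_track(
            track_id=7,
            n=47,
            x0=float(a.x[-1]) + 3.0,
            y0=float(a.y[-1]) + 2.0,
            frames=np.arange(54, 101),
        )
        merged = merge_track_fragments([a, b], max_frame_gap=10, max_join_distance_px=10)
        assert len(merged) == 1
        m = merged[0]
        assert m.track_id == 1
        assert len(m) == 97  # 100 frames minus the 3-frame hole
        assert m.frames[0] == 1 and m.frames[-1] == 100

    def test_overlapping_fragments_never_merge(self):
        a = straight_track(track_id=1, n=50, frames=np.arange(1, 51))
        b = straight_track(track_id=2, n=50, frames=np.arange(40, 90))
        merged = merge_track_fragments([a, b])
        assert len(merged) == 2

    def test_three_colinear_fragments_chain(self):
        # oracle: hand-merged single chain along y = 20 + 0.5 x
        def seg(tid, f0, f1):
            frames = np.arange(f0, f1 + 1)
            return Track(
                track_id=tid,
                frames=frames,
                x=frames * 2.0,
                y=20 + frames.astype(float),
            )

        parts = [seg(1, 1, 30), seg(2, 33, 60), seg(3, 64, 90)]
        merged = merge_track_fragments(parts, max_frame_gap=10, max_join_distance_px=20)
        assert len(merged) == 1
        hand_frames = np.concatenate(
            [np.arange(1, 31), np.arange(33, 61), np.arange(64, 91)]
        )
        assert np.array_equal(merged[0].frames, hand_frames)
        assert np.array_equal(merged[0].x, hand_frames * 2.0)

    def test_no_points_lost_or_duplicated(self):
        a = straight_track(track_id=1, n=10, frames=np.arange(1, 11))
        b = straight_track(
            track_id=2, n=10, x0=float(a.x[-1]), y0=float(a.y[-1]),
            frames=np.arange(12, 22),
        )
        merged = merge_track_fragments([a, b], max_frame_gap=5, max_join_distance_px=60)
        assert sum(len(t) for t in merged) == 20
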