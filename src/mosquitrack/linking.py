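"""Frame-to-frame data association: unlabelled detections -> identity tracks.

The linker walks frames in order and assigns each frame's detections to the
open tracks by minimum-total-distance one-to-one matching (Hungarian
algorithm), gated by a maximum displacement radius and a direction
continuity check. With well-separated individuals this reduces to plain
nearest-neighbour linking; when two tracks compete for one detection the
global assignment removes any dependence on processing order.

Tracks coast (stay open without gaining points) through short runs of
missed detections; a track unmatched for more than ``max_coast_frames``
consecutive frames is closed, which fragments a trajectory into multiple
records. :func:`merge_track_fragments` repairs that by greedily joining
fragments whose end/start frames and positions are compatible. The frame
holes left by coasting are filled later by spline interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detect import Detection, FrameDetections
from .errors import ParameterError
from .track import STATE_ACTIVE, STATE_CLOSED, Track


@dataclass(frozen=True)
class LinkParams:
    """Gating and continuity parameters for the linker.

    gating_radius_px
        Maximum allowed displacement between a track's last position and a
        candidate detection. Default 50 px, several mosquito body lengths
        per frame at 60 fps.
    max_coast_frames
        How many consecutive unmatched frames a track survives before it is
        closed. Default 30 (0.5 s at 60 fps).
    direction_window
        Number of recent displacements averaged to define the current
        heading. Default 3.
    max_turn_deg
        Maximum angle between the recent heading and the heading to a
        candidate detection. Default 120 degrees; mosquitoes turn sharply,
        so the gate only rejects near-reversals.
    resting_speed_px_per_frame
        Below this speed a displacement is treated as localisation jitter
        rather than motion: a track whose recent mean speed is below it
        counts as resting, and a candidate step below it counts as
        stopping; both are exempt from the direction gate, because the
        heading of a jitter-scale displacement carries no information.
        Default 3 px/frame, about three times a typical sub-pixel
        centroid noise scale.
    metric
        ``"euclidean"`` (default) or ``"per_axis"`` (Chebyshev: both axis
        displacements within the gate).
    """

    gating_radius_px: float = 50.0
    max_coast_frames: int = 30
    direction_window: int = 3
    max_turn_deg: float = 120.0
    resting_speed_px_per_frame: float = 3.0
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.gating_radius_px <= 0:
            raise ParameterError("gating_radius_px must be positive")
        if self.max_coast_frames < 0:
            raise ParameterError("max_coast_frames must be non-negative")
        if self.direction_window < 2:
            raise ParameterError("direction_window must be >= 2")
        if not 0.0 < self.max_turn_deg <= 180.0:
            raise ParameterError("max_turn_deg must be in (0, 180]")
        if self.metric not in ("euclidean", "per_axis"):
            raise ParameterError("metric must be 'euclidean' or 'per_axis'")


@dataclass
class Assignment:
    """Result of one frame's association step."""

    matches: list[tuple[int, int]]  # (track_id, detection index) pairs
    unmatched_tracks: list[int]  # track ids
    unmatched_detections: list[int]  # detection indices


def _distance(ax: float, ay: float, bx: float, by: float, metric: str) -> float:
    if metric == "per_axis":
        return max(abs(ax - bx), abs(ay - by))
    return math.hypot(ax - bx, ay - by)


def direction_consistency(
    track: Track, candidate: Detection, params: LinkParams
) -> bool:
    """Does extending ``track`` with ``candidate`` keep the heading plausible?

    Passes automatically when the track is too short to define a heading
    (< ``direction_window`` detected points) or is resting (recent mean
    speed below the resting threshold). Otherwise the angle between the
    mean recent heading and the heading to the candidate must not exceed
    ``max_turn_deg``.
    """
    det_idx = np.flatnonzero(track.detected_mask())
    if len(det_idx) < params.direction_window:
        return True
    recent = det_idx[-params.direction_window :]
    xs, ys, fs = track.x[recent], track.y[recent], track.frames[recent]
    dt = np.diff(fs).astype(float)
    vx = np.diff(xs) / dt
    vy = np.diff(ys) / dt
    mean_vx, mean_vy = float(vx.mean()), float(vy.mean())
    speed = math.hypot(mean_vx, mean_vy)
    if speed < params.resting_speed_px_per_frame:
        return True
    df = candidate.frame - int(fs[-1])
    if df <= 0:
        raise ParameterError("candidate frame must follow the track's last frame")
    cand_vx = (candidate.x - float(xs[-1])) / df
    cand_vy = (candidate.y - float(ys[-1])) / df
    cand_speed = math.hypot(cand_vx, cand_vy)
    if cand_speed < params.resting_speed_px_per_frame:
        # a step this small is indistinguishable from localisation jitter,
        # so its heading carries no information: slowing/stopping is always
        # an allowed continuation
        return True
    cos_angle = (mean_vx * cand_vx + mean_vy * cand_vy) / (speed * cand_speed)
    angle = math.degrees(math.acos(max(-1.0, min(1.0, cos_angle))))
    return angle <= params.max_turn_deg


def associate_frame(
    active_tracks: list[Track], dets: FrameDetections, params: LinkParams
) -> Assignment:
    """One-to-one partial assignment of detections to open tracks.

    A (track, detection) pair is admissible when the displacement from the
    track's last position is within the gating radius and the direction
    gate passes. Among admissible assignments of maximal size the total
    summed distance is minimised; exact-cost ties break toward the
    lexicographically smallest (track_id, detection index) pairing.
    """
    n_t, n_d = len(active_tracks), len(dets.detections)
    if n_t == 0 or n_d == 0:
        return Assignment(
            matches=[],
            unmatched_tracks=[t.track_id for t in active_tracks],
            unmatched_detections=list(range(n_d)),
        )

    order = sorted(range(n_t), key=lambda i: active_tracks[i].track_id)
    cost = np.full((n_t, n_d), np.inf)
    for rank, ti in enumerate(order):
        track = active_tracks[ti]
        lx, ly = float(track.x[-1]), float(track.y[-1])
        for di, det in enumerate(dets.detections):
            d = _distance(lx, ly, det.x, det.y, params.metric)
            if d <= params.gating_radius_px and direction_consistency(
                track, det, params
            ):
                cost[ti, di] = d

    admissible = np.isfinite(cost)
    if not admissible.any():
        return Assignment(
            matches=[],
            unmatched_tracks=[t.track_id for t in active_tracks],
            unmatched_detections=list(range(n_d)),
        )

    # Pad with a large constant so the Hungarian solve first maximises the
    # number of admissible matches, then minimises their summed distance.
    big = params.gating_radius_px * (n_t + n_d + 1) * 4.0
    padded = np.where(admissible, cost, big)
    # Infinitesimal lexicographic perturbation: breaks exact-cost ties
    # toward small (track_id, detection index) without affecting any
    # genuine cost difference.
    eps = 1e-9 * params.gating_radius_px / (n_t * n_d + 1)
    for rank, ti in enumerate(order):
        padded[ti] = padded[ti] + eps * (rank * n_d + np.arange(n_d))

    rows, cols = linear_sum_assignment(padded)
    matches: list[tuple[int, int]] = []
    matched_t: set[int] = set()
    matched_d: set[int] = set()
    for ti, di in zip(rows, cols):
        if admissible[ti, di]:
            matches.append((active_tracks[ti].track_id, int(di)))
            matched_t.add(ti)
            matched_d.add(int(di))
    matches.sort()
    return Assignment(
        matches=matches,
        unmatched_tracks=sorted(
            active_tracks[ti].track_id for ti in range(n_t) if ti not in matched_t
        ),
        unmatched_detections=[di for di in range(n_d) if di not in matched_d],
    )


def assignment_cost(
    active_tracks: list[Track],
    dets: FrameDetections,
    assignment: Assignment,
    params: LinkParams,
) -> float:
    """Total summed distance of an assignment's matches."""
    by_id = {t.track_id: t for t in active_tracks}
    total = 0.0
    for tid, di in assignment.matches:
        track = by_id[tid]
        det = dets.detections[di]
        total += _distance(
            float(track.x[-1]), float(track.y[-1]), det.x, det.y, params.metric
        )
    return total


def _append_point(track: Track, det: Detection) -> Track:
    return Track(
        track_id=track.track_id,
        frames=np.append(track.frames, det.frame),
        x=np.append(track.x, det.x),
        y=np.append(track.y, det.y),
        interpolated=np.append(track.interpolated, False),
        state=STATE_ACTIVE,
    )


def build_tracks(
    frames: list[FrameDetections], params: LinkParams | None = None
) -> list[Track]:
    """Link per-frame detections into identity-consistent tracks.

    Frames are processed in ascending order. Matched detections extend
    their tracks; every unmatched detection opens a new track immediately
    (all individuals are tracked from their first appearance); a track
    unmatched for more than ``max_coast_frames`` consecutive frames is
    closed. Every detection ends up in exactly one track.
    """
    params = params or LinkParams()
    frames = sorted(frames, key=lambda fd: fd.frame)
    active: list[Track] = []
    closed: list[Track] = []
    next_id = 1

    for fd in frames:
        # close tracks that have coasted too long before this frame
        still_active: list[Track] = []
        for track in active:
            if fd.frame - int(track.frames[-1]) - 1 > params.max_coast_frames:
                closed.append(track.copy(state=STATE_CLOSED))
            else:
                still_active.append(track)
        active = still_active

        assignment = associate_frame(active, fd, params)
        by_id = {t.track_id: i for i, t in enumerate(active)}
        for tid, di in assignment.matches:
            idx = by_id[tid]
            active[idx] = _append_point(active[idx], fd.detections[di])
        for di in assignment.unmatched_detections:
            det = fd.detections[di]
            active.append(
                Track(
                    track_id=next_id,
                    frames=np.array([det.frame]),
                    x=np.array([det.x]),
                    y=np.array([det.y]),
                    interpolated=np.array([False]),
                    state=STATE_ACTIVE,
                )
            )
            next_id += 1

    closed.extend(t.copy(state=STATE_CLOSED) for t in active)
    closed.sort(key=lambda t: t.track_id)
    return closed


def merge_track_fragments(
    tracks: list[Track],
    max_frame_gap: int = 60,
    max_join_distance_px: float = 50.0,
) -> list[Track]:
    """Greedily rejoin fragments of the same trajectory.

    A pair (A ends, B starts) is joinable when ``0 < startB - endA <=
    max_frame_gap`` and the endpoint distance is at most
    ``max_join_distance_px``. Joins are applied smallest endpoint distance
    first (ties toward smaller ids); the merged track keeps the earlier
    fragment's id. Fragments with overlapping frame ranges are never
    merged. No point is duplicated or lost.
    """
    merged = {t.track_id: t.copy() for t in tracks}

    while True:
        candidates: list[tuple[float, int, int]] = []
        for a in merged.values():
            for b in merged.values():
                if a.track_id == b.track_id:
                    continue
                gap = int(b.frames[0]) - int(a.frames[-1])
                if not 0 < gap <= max_frame_gap:
                    continue
                d = math.hypot(
                    float(a.x[-1]) - float(b.x[0]), float(a.y[-1]) - float(b.y[0])
                )
                if d <= max_join_distance_px:
                    candidates.append((d, a.track_id, b.track_id))
        if not candidates:
            break
        _, aid, bid = min(candidates)
        a, b = merged[aid], merged[bid]
        merged[aid] = Track(
            track_id=aid,
            frames=np.concatenate([a.frames, b.frames]),
            x=np.concatenate([a.x, b.x]),
            y=np.concatenate([a.y, b.y]),
            interpolated=np.concatenate([a.interpolated, b.interpolated]),
            state=STATE_CLOSED,
        )
        del merged[bid]

    return sorted(merged.values(), key=lambda t: t.track_id)
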