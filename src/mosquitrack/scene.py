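"""Synthetic flight-cage scenes for benchmarking the tracking pipeline.

Emulates a fixed-camera recording of a mosquito cage: a small arena viewed
at constant frame rate, a handful of individuals in smooth wandering
flight, many more resting on the walls, sub-pixel detector noise, and
localized regions (cage edges, a feeding bottle, dark folds in the
background net) where the detector tends to miss the animal entirely.

The flight model is a correlated random walk: per frame the heading turns
by a wrapped-Gaussian angle whose concentration is set by
``turn_smoothness`` (the circular autocorrelation of heading), the speed is
drawn uniformly from ``speed_range_px_per_frame``, and trajectories reflect
specularly off the arena walls. This reproduces the smooth-but-wandering
look of real mosquito flight with two interpretable knobs; no claim is made
of kinematic realism beyond that.

Everything is driven by a single integer seed: per-individual random
streams are spawned deterministically from the scene seed, so an identical
:class:`SceneSpec` always yields bit-identical tracks, detections and
rendered frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detect import Detection, FrameDetections
from .errors import ParameterError, PlacementError
from .track import Track

_MIN_ANCHOR_SEPARATION_PX = 10.0


@dataclass(frozen=True)
class ArenaSpec:
    """Camera view of the cage: frame geometry in pixels and frame rate."""

    width_px: int = 640
    height_px: int = 512
    fps: float = 60.0

    def __post_init__(self) -> None:
        if self.width_px < 16 or self.height_px < 16:
            raise ParameterError("arena must be at least 16x16 px")
        if self.fps <= 0:
            raise ParameterError("fps must be positive")


@dataclass(frozen=True)
class ClutterRegion:
    """Axis-aligned rectangle where detections drop out with probability p.

    Bounds are half-open pixel intervals [x_min, x_max) x [y_min, y_max).
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    dropout_prob: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ParameterError("clutter rectangle is empty")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ParameterError("dropout probability must be in [0, 1]")

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterization of one synthetic scene.

    Defaults mirror the benchmark setting the package is built around: a
    640x512 px arena at 60 fps, ~9 s (540 frames), a few fliers among many
    resting individuals, sub-pixel localisation noise.
    """

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    n_frames: int = 540
    n_flying: int = 2
    n_resting: int = 3
    speed_range_px_per_frame: tuple[float, float] = (1.0, 6.0)
    turn_smoothness: float = 0.95
    noise_sigma_px: float = 0.5
    clutter_regions: tuple[ClutterRegion, ...] = ()
    resting_jitter_px: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be positive")
        if self.n_flying < 0 or self.n_resting < 0:
            raise ParameterError("individual counts must be non-negative")
        lo, hi = self.speed_range_px_per_frame
        if lo < 0 or hi < lo:
            raise ParameterError("speed_range must satisfy 0 <= min <= max")
        if not 0.0 < self.turn_smoothness <= 1.0:
            raise ParameterError("turn_smoothness must be in (0, 1]")
        if self.noise_sigma_px < 0 or self.resting_jitter_px < 0:
            raise ParameterError("noise scales must be non-negative")
        for region in self.clutter_regions:
            if not (
                0 <= region.x_min
                and region.x_max <= self.arena.width_px
                and 0 <= region.y_min
                and region.y_max <= self.arena.height_px
            ):
                raise ParameterError("clutter rectangle outside arena bounds")


@dataclass
class GroundTruthScene:
    """True trajectories of every individual in a synthetic scene."""

    spec: SceneSpec
    true_tracks: list[Track]
    flying_flags: list[bool]

    def __post_init__(self) -> None:
        arena = self.spec.arena
        for track in self.true_tracks:
            if len(track) != self.spec.n_frames:
                raise ParameterError("every true track must cover all frames")
            if (
                track.x.min() < 0
                or track.x.max() >= arena.width_px
                or track.y.min() < 0
                or track.y.max() >= arena.height_px
            ):
                raise ParameterError("true positions must lie inside the arena")


def _turn_sigma(turn_smoothness: float) -> float:
    # wrapped-normal concentration: mean resultant length rho = exp(-s^2/2)
    if turn_smoothness >= 1.0:
        return 0.0
    return math.sqrt(-2.0 * math.log(turn_smoothness))


def _reflect(value: float, low: float, high: float) -> float:
    """Fold ``value`` into [low, high) by specular reflection."""
    span = high - low
    v = (value - low) % (2.0 * span)
    if v >= span:
        v = 2.0 * span - v
    return min(low + v, np.nextafter(high, low))


def sample_flight_trajectory(
    arena: ArenaSpec,
    n_frames: int,
    speed_range: tuple[float, float],
    turn_smoothness: float,
    seed: int | np.random.Generator,
) -> Track:
    """Simulate one smooth flight as a correlated random walk.

    Successive displacements have magnitude within ``speed_range``; the
    position reflects off the arena walls and never leaves the arena.
    Identical seeds give identical tracks.
    """
    if n_frames < 2:
        raise ParameterError("a flight needs at least 2 frames")
    lo, hi = speed_range
    if lo < 0 or hi < lo:
        raise ParameterError("speed_range must satisfy 0 <= min <= max")
    if not 0.0 < turn_smoothness <= 1.0:
        raise ParameterError("turn_smoothness must be in (0, 1]")
    rng = np.random.default_rng(seed)

    w, h = float(arena.width_px), float(arena.height_px)
    # start away from the walls so the first steps rarely reflect
    x = rng.uniform(0.1 * w, 0.9 * w)
    y = rng.uniform(0.1 * h, 0.9 * h)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    sigma = _turn_sigma(turn_smoothness)

    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    xs[0], ys[0] = x, y
    for i in range(1, n_frames):
        heading += rng.normal(0.0, sigma) if sigma > 0 else 0.0
        speed = rng.uniform(lo, hi)
        nx = x + speed * math.cos(heading)
        ny = y + speed * math.sin(heading)
        if not 0.0 <= nx < w:
            heading = math.pi - heading
            nx = _reflect(nx, 0.0, w)
        if not 0.0 <= ny < h:
            heading = -heading
            ny = _reflect(ny, 0.0, h)
        x, y = nx, ny
        xs[i], ys[i] = x, y
    frames = np.arange(1, n_frames + 1)
    return Track(track_id=1, frames=frames, x=xs, y=ys)


def sample_resting_positions(
    arena: ArenaSpec,
    n_resting: int,
    resting_jitter_px: float,
    n_frames: int,
    seed: int | np.random.Generator,
) -> list[Track]:
    """Place resting individuals at well-separated anchors with jitter.

    Anchors are rejection-sampled to be pairwise at least 10 px apart
    (resting mosquitoes on a net do not overlap at this image scale); each
    per-frame position is the anchor plus isotropic Gaussian jitter of
    scale ``resting_jitter_px``, clipped to the arena.
    """
    if n_resting < 0:
        raise ParameterError("n_resting must be non-negative")
    if n_resting == 0:
        return []
    rng = np.random.default_rng(seed)
    w, h = float(arena.width_px), float(arena.height_px)

    anchors: list[tuple[float, float]] = []
    max_attempts = 1000 * n_resting
    attempts = 0
    margin = 2.0
    while len(anchors) < n_resting:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {n_resting} anchors with "
                f"{_MIN_ANCHOR_SEPARATION_PX} px separation in a "
                f"{arena.width_px}x{arena.height_px} arena"
            )
        cand = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
        if all(
            math.hypot(cand[0] - a[0], cand[1] - a[1]) >= _MIN_ANCHOR_SEPARATION_PX
            for a in anchors
        ):
            anchors.append(cand)

    frames = np.arange(1, n_frames + 1)
    tracks = []
    for i, (ax, ay) in enumerate(anchors):
        if resting_jitter_px > 0:
            jx = rng.normal(0.0, resting_jitter_px, size=n_frames)
            jy = rng.normal(0.0, resting_jitter_px, size=n_frames)
        else:
            jx = np.zeros(n_frames)
            jy = np.zeros(n_frames)
        xs = np.clip(ax + jx, 0.0, np.nextafter(w, 0.0))
        ys = np.clip(ay + jy, 0.0, np.nextafter(h, 0.0))
        tracks.append(Track(track_id=i + 1, frames=frames, x=xs, y=ys))
    return tracks


def generate_scene(spec: SceneSpec) -> GroundTruthScene:
    """Generate all ground-truth tracks for a scene specification.

    Flying individuals get ids 1..n_flying, resting individuals follow.
    """
    root = np.random.SeedSequence(spec.seed)
    flight_seeds, rest_seed = root.spawn(spec.n_flying), root.spawn(1)[0]
    tracks: list[Track] = []
    flags: list[bool] = []
    for i, child in enumerate(flight_seeds):
        track = sample_flight_trajectory(
            spec.arena,
            spec.n_frames,
            spec.speed_range_px_per_frame,
            spec.turn_smoothness,
            np.random.default_rng(child),
        )
        track.track_id = i + 1
        tracks.append(track)
        flags.append(True)
    resting = sample_resting_positions(
        spec.arena,
        spec.n_resting,
        spec.resting_jitter_px,
        spec.n_frames,
        np.random.default_rng(rest_seed),
    )
    for track in resting:
        track.track_id = len(tracks) + 1
        tracks.append(track)
        flags.append(False)
    return GroundTruthScene(spec=spec, true_tracks=tracks, flying_flags=flags)


def apply_observation_model(
    scene: GroundTruthScene,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[FrameDetections], np.ndarray]:
    """Turn true positions into noisy, anonymous, clutter-censored detections.

    For each frame and individual a detection is emitted at the true
    position plus isotropic Gaussian noise (``noise_sigma_px``) — unless the
    true position lies inside a clutter rectangle and an independent
    Bernoulli draw with that rectangle's dropout probability deletes it.

    Returns
    -------
    detections
        One :class:`FrameDetections` per frame (frames with zero surviving
        detections still appear, with an empty list). Detections carry no
        identity labels; within a frame they are ordered by individual
        index, which downstream linkers must not rely on.
    miss_mask
        Boolean array of shape (n_individuals, n_frames); True where the
        individual's detection was deleted.
    """
    spec = scene.spec
    if seed is None:
        # derive the observation stream from the scene seed, distinct from
        # the trajectory streams
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1000)[-1])
    else:
        rng = np.random.default_rng(seed)

    n_ind = len(scene.true_tracks)
    n_frames = spec.n_frames
    miss_mask = np.zeros((n_ind, n_frames), dtype=bool)
    w = np.nextafter(float(spec.arena.width_px), 0.0)
    h = np.nextafter(float(spec.arena.height_px), 0.0)

    per_frame: list[FrameDetections] = []
    for fi in range(n_frames):
        frame = fi + 1
        dets: list[Detection] = []
        for ii, track in enumerate(scene.true_tracks):
            tx, ty = float(track.x[fi]), float(track.y[fi])
            dropped = False
            for region in spec.clutter_regions:
                if region.contains(tx, ty) and rng.random() < region.dropout_prob:
                    dropped = True
                    break
            if dropped:
                miss_mask[ii, fi] = True
                continue
            if spec.noise_sigma_px > 0:
                ox = tx + rng.normal(0.0, spec.noise_sigma_px)
                oy = ty + rng.normal(0.0, spec.noise_sigma_px)
            else:
                ox, oy = tx, ty
            dets.append(
                Detection(
                    frame=frame,
                    x=float(np.clip(ox, 0.0, w)),
                    y=float(np.clip(oy, 0.0, h)),
                    confidence=1.0,
                )
            )
        per_frame.append(FrameDetections(frame=frame, detections=dets))
    return per_frame, miss_mask


def render_frames(
    scene: GroundTruthScene,
    blob_radius_px: float = 3.0,
    foreground_level: int = 30,
    background_level: int = 200,
    detections: list[FrameDetections] | None = None,
) -> np.ndarray:
    """Render 8-bit grayscale frames with a dark blob per individual.

    Each frame is a uniform ``background_level`` image with an isotropic
    dark disc of the given radius at each individual's position (the true
    position, or — when ``detections`` from :func:`apply_observation_model`
    are passed — the noisy, possibly-missing observed positions). Disc
    edges are anti-aliased by pixel-coverage weighting so the
    intensity-weighted centroid of a rendered blob reproduces the requested
    sub-pixel position. Overlapping blobs simply merge (darkest wins),
    which is the documented occlusion failure mode, not an error.
    """
    if blob_radius_px < 1:
        raise ParameterError("blob_radius_px must be >= 1")
    for level in (foreground_level, background_level):
        if not 0 <= level <= 255:
            raise ParameterError("intensity levels must be in [0, 255]")
    spec = scene.spec
    h, w = spec.arena.height_px, spec.arena.width_px
    stack = np.full((spec.n_frames, h, w), float(background_level))

    if detections is None:
        positions_per_frame: list[list[tuple[float, float]]] = [
            [(float(t.x[fi]), float(t.y[fi])) for t in scene.true_tracks]
            for fi in range(spec.n_frames)
        ]
    else:
        positions_per_frame = [[(d.x, d.y) for d in fd.detections] for fd in detections]

    r = float(blob_radius_px)
    pad = int(math.ceil(r)) + 1
    for fi, positions in enumerate(positions_per_frame):
        img = stack[fi]
        for cx, cy in positions:
            x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
            y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dist = np.hypot(xx - cx, yy - cy)
            # coverage in [0,1]: 1 inside the disc, linear falloff over 1 px
            coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)
            shaded = (1 - coverage) * background_level + coverage * foreground_level
            combine = np.minimum if foreground_level < background_level else np.maximum
            combine(img[y0:y1, x0:x1], shaded, out=img[y0:y1, x0:x1])
    return np.clip(np.rint(stack), 0, 255).astype(np.uint8)
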