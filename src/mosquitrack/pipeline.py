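"""End-to-end pipeline: simulate/ingest -> link -> merge -> fill -> evaluate.

A :class:`PipelineConfig` (YAML-serialisable, unknown keys rejected)
carries every tunable: arena geometry, the scene generator parameters,
the ingestion confidence threshold, linker gating, the spline gap limit
and the evaluation tolerance. Given a config and its seed the whole run
is deterministic: track files and the report are byte-identical across
runs.

Per-stage counters (detections in/out, tracks opened/closed/merged,
frames interpolated) are logged so that clutter- and reflection-induced
failure modes show up in the run log, not just in the final accuracy.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import linear_sum_assignment

from . import io as mio
from .detect import FrameDetections, ingest_external_detections
from .errors import ParameterError, PipelineError
from .gapfill import DEFAULT_MAX_SPLINE_GAP, fill_track_gaps
from .linking import LinkParams, build_tracks, merge_track_fragments
from .metrics import (
    DEFAULT_TOLERANCE_PX,
    MetricReport,
    pair_trajectories,
    scenario_report,
)
from .scene import (
    ArenaSpec,
    ClutterRegion,
    GroundTruthScene,
    SceneSpec,
    apply_observation_model,
    generate_scene,
)
from .track import Track

logger = logging.getLogger("mosquitrack")


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on."""

    scene: SceneSpec = field(default_factory=SceneSpec)
    min_confidence: float = 0.7
    link: LinkParams = field(default_factory=LinkParams)
    merge_max_frame_gap: int = 60
    merge_max_join_distance_px: float = 50.0
    max_spline_gap: int = DEFAULT_MAX_SPLINE_GAP
    tolerance_px: float = DEFAULT_TOLERANCE_PX
    detections_csv: str | None = None  # external detections; None => simulate
    output_dir: str = "mosquitrack_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"]["arena"] = dataclasses.asdict(self.scene.arena)
        d["scene"]["clutter_regions"] = [
            dataclasses.asdict(r) for r in self.scene.clutter_regions
        ]
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "scene" in data and isinstance(data["scene"], dict):
            scene = dict(data["scene"])
            scene_known = {f.name for f in dataclasses.fields(SceneSpec)}
            bad = set(scene) - scene_known
            if bad:
                raise ParameterError(f"unknown scene keys: {sorted(bad)}")
            if "arena" in scene and isinstance(scene["arena"], dict):
                scene["arena"] = ArenaSpec(**scene["arena"])
            if "clutter_regions" in scene:
                scene["clutter_regions"] = tuple(
                    ClutterRegion(**r) if isinstance(r, dict) else r
                    for r in scene["clutter_regions"]
                )
            if "speed_range_px_per_frame" in scene:
                scene["speed_range_px_per_frame"] = tuple(
                    scene["speed_range_px_per_frame"]
                )
            data["scene"] = SceneSpec(**scene)
        if "link" in data and isinstance(data["link"], dict):
            data["link"] = LinkParams(**data["link"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


@dataclass
class PipelineResult:
    """Artifacts of one run kept in memory."""

    config: PipelineConfig
    scene: GroundTruthScene | None
    detections: list[FrameDetections]
    tracks: list[Track]
    report: MetricReport | None
    timings_s: dict[str, float]


def match_tracks_to_truth(
    est_tracks: list[Track],
    gt_tracks: list[Track],
    match_radius_px: float = DEFAULT_TOLERANCE_PX,
) -> dict[int, int]:
    """One-to-one map (ground-truth index -> estimated track index).

    Each (ground truth, estimate) pair is scored by the number of shared
    frames where the Euclidean error is below ``match_radius_px`` (the
    frames that would count as accurately tracked), with the mean error
    over shared frames as an infinitesimal tie-break; the
    maximum-total-score one-to-one assignment decides correspondence.
    Pairs sharing no close frame are never matched.
    """
    if not est_tracks or not gt_tracks:
        return {}
    big = 1e12
    cost = np.full((len(gt_tracks), len(est_tracks)), big)
    for gi, gt in enumerate(gt_tracks):
        for ei, est in enumerate(est_tracks):
            common, gidx, eidx = np.intersect1d(
                gt.frames, est.frames, return_indices=True
            )
            if len(common) == 0:
                continue
            d = np.hypot(gt.x[gidx] - est.x[eidx], gt.y[gidx] - est.y[eidx])
            n_close = int((d < match_radius_px).sum())
            if n_close == 0:
                continue
            cost[gi, ei] = -float(n_close) + float(d.mean()) / big
    rows, cols = linear_sum_assignment(cost)
    return {
        int(gi): int(ei)
        for gi, ei in zip(rows, cols)
        if cost[gi, ei] < big
    }


def evaluate_tracks(
    est_tracks: list[Track],
    gt_tracks: list[Track],
    flying_flags: list[bool],
    tol_px: float = DEFAULT_TOLERANCE_PX,
) -> MetricReport:
    """Pair estimated tracks with ground truth and build the report.

    Ground-truth individuals with no matching estimated track score 0%
    accuracy (every frame missing).
    """
    matching = match_tracks_to_truth(est_tracks, gt_tracks)
    pairs = []
    for gi, gt in enumerate(gt_tracks):
        if gi in matching:
            pairs.append(pair_trajectories(est_tracks[matching[gi]], gt))
        else:
            from .metrics import TrajectoryPair

            pairs.append(
                TrajectoryPair(
                    frames=gt.frames.copy(),
                    est_x=np.full(len(gt), np.nan),
                    est_y=np.full(len(gt), np.nan),
                    gt_x=gt.x.copy(),
                    gt_y=gt.y.copy(),
                )
            )
    return scenario_report(pairs, flying_flags, tol_px)


def run_pipeline(
    config: PipelineConfig, write_outputs: bool = True
) -> PipelineResult:
    """Execute the full pipeline described by ``config``.

    Stages: simulate (or ingest external detections) -> link -> merge
    fragments -> fill gaps -> evaluate (when ground truth exists). Any
    stage error aborts with the stage name and cause.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    timings: dict[str, float] = {}
    out = Path(config.output_dir)

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    scene: GroundTruthScene | None = None
    with _stage("detect"):
        if config.detections_csv is not None:
            detections = ingest_external_detections(
                config.detections_csv, min_confidence=config.min_confidence
            )
            n_in = sum(len(fd) for fd in detections)
            logger.info("ingested %d detections from %s", n_in, config.detections_csv)
        else:
            scene = generate_scene(config.scene)
            detections, miss_mask = apply_observation_model(scene)
            logger.info(
                "simulated %d individuals over %d frames; %d detections, "
                "%d clutter misses",
                len(scene.true_tracks),
                config.scene.n_frames,
                sum(len(fd) for fd in detections),
                int(miss_mask.sum()),
            )

    with _stage("link"):
        tracks = build_tracks(detections, config.link)
        logger.info("linked %d raw tracks", len(tracks))

    with _stage("merge"):
        tracks = merge_track_fragments(
            tracks,
            max_frame_gap=config.merge_max_frame_gap,
            max_join_distance_px=config.merge_max_join_distance_px,
        )
        logger.info("after fragment merging: %d tracks", len(tracks))

    with _stage("fill"):
        filled = []
        n_interp = 0
        for track in tracks:
            if int(track.detected_mask().sum()) >= 2:
                track = fill_track_gaps(track, config.max_spline_gap)
            n_interp += int(track.interpolated.sum())
            filled.append(track)
        tracks = filled
        logger.info("interpolated %d missing frames", n_interp)

    report: MetricReport | None = None
    if scene is not None:
        with _stage("evaluate"):
            report = evaluate_tracks(
                tracks,
                scene.true_tracks,
                scene.flying_flags,
                tol_px=config.tolerance_px,
            )
            logger.info(
                "overall mean accuracy %.2f%%",
                report.overall_mean_accuracy_pct,
            )

    if write_outputs:
        with _stage("write"):
            out.mkdir(parents=True, exist_ok=True)
            mio.write_tracks_dir(tracks, out / "tracks")
            mio.write_detections_csv(detections, out / "detections.csv")
            if scene is not None:
                mio.write_tracks_dir(scene.true_tracks, out / "ground_truth")
            if report is not None:
                import json

                (out / "report.json").write_text(
                    json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
                    encoding="utf-8",
                )
                (out / "report.txt").write_text(
                    report.to_table() + "\n", encoding="utf-8"
                )

    return PipelineResult(
        config=config,
        scene=scene,
        detections=detections,
        tracks=tracks,
        report=report,
        timings_s=timings,
    )
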