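"""Per-frame centroid detections: external-detector ingestion and a
reference blob detector.

The pipeline is detector-agnostic: any upstream instance-segmentation or
object detector can feed it through a plain CSV of per-frame centroids
(``frame,x,y,confidence``). Rows below a confidence threshold (default
0.7, the conventional proposal cutoff) are dropped at ingestion.

For rendered or other high-contrast footage a classical detector is built
in: per-pixel temporal-median background estimation, absolute-difference
thresholding, 8-connected component labelling, and intensity-weighted
centroids with an area band to reject noise specks and large artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InsufficientDataError, ParseError, ValidationError

DEFAULT_MIN_CONFIDENCE = 0.7
DEFAULT_MIN_AREA_PX = 3
DEFAULT_MAX_AREA_PX = 400

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Detection:
    """One candidate centroid in one frame (1-based frame numbering)."""

    frame: int
    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValidationError("frame numbers are 1-based positive integers")
        if self.x < 0 or self.y < 0:
            raise ValidationError("detection coordinates must be non-negative")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError("confidence must be in [0, 1]")


@dataclass
class FrameDetections:
    """All detections of one frame; the list may be empty."""

    frame: int
    detections: list[Detection]

    def __post_init__(self) -> None:
        for det in self.detections:
            if det.frame != self.frame:
                raise ValidationError(
                    f"detection frame {det.frame} inconsistent with group "
                    f"frame {self.frame}"
                )

    def __len__(self) -> int:
        return len(self.detections)


def group_by_frame(detections: list[Detection]) -> list[FrameDetections]:
    """Group a flat detection list by ascending frame number."""
    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)
    return [FrameDetections(frame=f, detections=by_frame[f]) for f in sorted(by_frame)]


def ingest_external_detections(
    path: str | Path,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[FrameDetections]:
    """Read a detection CSV, apply the confidence threshold, group by frame.

    Rows with ``confidence < min_confidence`` are dropped; duplicated
    ``(frame, x, y)`` rows collapse to one. Malformed rows raise
    :class:`ParseError` naming the 1-based file line; negative coordinates
    raise :class:`ValidationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path} is empty (expected header frame,x,y,confidence)")
    expected = ["frame", "x", "y"]
    if list(df.columns[:3]) != expected:
        raise ParseError(
            f"{path}: header must start with 'frame,x,y' "
            f"(got {list(df.columns)})",
            line=1,
        )
    has_conf = "confidence" in df.columns

    detections: list[Detection] = []
    seen: set[tuple[int, float, float]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        try:
            frame = int(row.frame)
            x = float(row.x)
            y = float(row.y)
            conf = float(row.confidence) if has_conf and row.confidence != "" else 1.0
        except (TypeError, ValueError) as exc:
            raise ParseError(f"malformed detection row ({exc})", line=line)
        if x < 0 or y < 0:
            raise ValidationError(f"line {line}: negative coordinates ({x}, {y})")
        if conf < min_confidence:
            continue
        key = (frame, x, y)
        if key in seen:
            continue
        seen.add(key)
        try:
            detections.append(Detection(frame=frame, x=x, y=y, confidence=conf))
        except ValidationError as exc:
            raise ParseError(str(exc), line=line)
    return group_by_frame(detections)


def estimate_background(frames: np.ndarray, sample_stride: int = 1) -> np.ndarray:
    """Per-pixel temporal median over every ``sample_stride``-th frame.

    The median is robust to transient foreground (a mosquito occupies any
    given pixel for only a few frames), so it recovers the static scene.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValidationError("expected a (n_frames, height, width) stack")
    if sample_stride < 1:
        raise ValidationError("sample_stride must be >= 1")
    sampled = frames[::sample_stride]
    if sampled.shape[0] < 3:
        raise InsufficientDataError(
            f"need >= 3 sampled frames, got {sampled.shape[0]}"
        )
    return np.median(sampled, axis=0)


def detect_blobs(
    frame_image: np.ndarray,
    background: np.ndarray,
    frame: int = 1,
    diff_threshold: float = 20.0,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    max_area_px: int = DEFAULT_MAX_AREA_PX,
) -> FrameDetections:
    """Detect compact blobs by background subtraction.

    Pixels with ``|frame - background| >= diff_threshold`` are foreground;
    8-connected components with area inside ``[min_area_px, max_area_px]``
    become detections at their intensity-weighted (by absolute difference)
    centroids, confidence 1.0.
    """
    frame_image = np.asarray(frame_image, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if frame_image.shape != background.shape:
        raise ValidationError(
            f"frame shape {frame_image.shape} != background shape "
            f"{background.shape}"
        )
    if not 0 < min_area_px <= max_area_px:
        raise ValidationError("need 0 < min_area_px <= max_area_px")

    diff = np.abs(frame_image - background)
    mask = diff >= diff_threshold
    labels, n_labels = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    detections: list[Detection] = []
    if n_labels:
        areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n_labels + 1))
        centroids = ndimage.center_of_mass(diff, labels, np.arange(1, n_labels + 1))
        for area, (cy, cx) in zip(areas, centroids):
            if min_area_px <= area <= max_area_px:
                detections.append(
                    Detection(frame=frame, x=float(cx), y=float(cy), confidence=1.0)
                )
    detections.sort(key=lambda d: (d.x, d.y))
    return FrameDetections(frame=frame, detections=detections)


def detect_stack(
    frames: np.ndarray,
    sample_stride: int = 1,
    diff_threshold: float = 20.0,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    max_area_px: int = DEFAULT_MAX_AREA_PX,
) -> list[FrameDetections]:
    """Run background estimation + blob detection over a whole stack."""
    background = estimate_background(frames, sample_stride=sample_stride)
    return [
        detect_blobs(
            img,
            background,
            frame=i + 1,
            diff_threshold=diff_threshold,
            min_area_px=min_area_px,
            max_area_px=max_area_px,
        )
        for i, img in enumerate(np.asarray(frames))
    ]
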