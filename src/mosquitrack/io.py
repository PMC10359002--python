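"""On-disk formats: per-individual track text files, detection CSVs,
scene/pipeline YAML configs, and rendered frame stacks.

Track files are plain text, one per individual: ``#``-prefixed header
lines, then whitespace-separated rows ``frame x y provenance``. Frame
numbers are 1-based and coordinates are written at full precision
(``repr``), so write -> read is an exact round trip. All writers emit
UTF-8 with ``\\n`` newlines and locale-independent number formatting.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detect import Detection, FrameDetections, group_by_frame
from .errors import ParseError, ValidationError
from .track import PROVENANCE_DETECTED, PROVENANCE_INTERPOLATED, Track

_PROVENANCE_VALUES = {PROVENANCE_DETECTED, PROVENANCE_INTERPOLATED}


def write_track_file(track: Track, path: str | Path) -> None:
    """Write one track as a text file (``frame x y provenance`` rows)."""
    path = Path(path)
    lines = [f"# track_id {track.track_id}", "# columns: frame x y provenance"]
    for f, x, y, prov in zip(track.frames, track.x, track.y, track.provenance):
        lines.append(f"{int(f)} {float(x)!r} {float(y)!r} {prov}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_track_file(path: str | Path) -> Track:
    """Parse a track text file; raises :class:`ParseError` with the line."""
    path = Path(path)
    track_id = 0
    frames: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    interp: list[bool] = []
    prev_frame = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "track_id":
                try:
                    track_id = int(parts[1])
                except ValueError:
                    raise ParseError("bad track_id header", line=lineno)
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(
                f"expected 4 columns 'frame x y provenance', got {len(parts)}",
                line=lineno,
            )
        try:
            frame = int(parts[0])
            x = float(parts[1])
            y = float(parts[2])
        except ValueError as exc:
            raise ParseError(f"malformed row ({exc})", line=lineno)
        if parts[3] not in _PROVENANCE_VALUES:
            raise ParseError(f"unknown provenance {parts[3]!r}", line=lineno)
        if prev_frame is not None and frame <= prev_frame:
            raise ParseError(
                f"frame {frame} not greater than previous frame {prev_frame}",
                line=lineno,
            )
        prev_frame = frame
        frames.append(frame)
        xs.append(x)
        ys.append(y)
        interp.append(parts[3] == PROVENANCE_INTERPOLATED)
    if not frames:
        raise ParseError(f"{path} contains no track points")
    return Track(
        track_id=track_id if track_id >= 1 else 1,
        frames=np.array(frames),
        x=np.array(xs),
        y=np.array(ys),
        interpolated=np.array(interp),
    )


def write_tracks_dir(tracks: list[Track], directory: str | Path) -> list[Path]:
    """Write one ``track_<id>.txt`` per track into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for track in tracks:
        p = directory / f"track_{track.track_id:04d}.txt"
        write_track_file(track, p)
        paths.append(p)
    return paths


def read_tracks_dir(directory: str | Path) -> list[Track]:
    """Read every ``track_*.txt`` in a directory, sorted by filename."""
    directory = Path(directory)
    paths = sorted(directory.glob("track_*.txt"))
    if not paths:
        raise ParseError(f"no track_*.txt files in {directory}")
    return [read_track_file(p) for p in paths]


def write_detections_csv(
    frames: list[FrameDetections], path: str | Path
) -> None:
    """Write grouped detections as ``frame,x,y,confidence`` CSV."""
    rows = []
    for fd in sorted(frames, key=lambda fd: fd.frame):
        for det in fd.detections:
            rows.append(
                {
                    "frame": det.frame,
                    "x": repr(float(det.x)),
                    "y": repr(float(det.y)),
                    "confidence": repr(float(det.confidence)),
                }
            )
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "confidence"])
    df.to_csv(path, index=False, lineterminator="\n")


def read_detections_csv(path: str | Path) -> list[FrameDetections]:
    """Read a detection CSV without any confidence filtering.

    Use :func:`mosquitrack.detect.ingest_external_detections` to apply the
    confidence threshold and deduplication on ingestion.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    if list(df.columns[:3]) != ["frame", "x", "y"]:
        raise ParseError(f"{path}: header must start with 'frame,x,y'", line=1)
    dets = [
        Detection(
            frame=int(row.frame),
            x=float(row.x),
            y=float(row.y),
            confidence=float(getattr(row, "confidence", 1.0)),
        )
        for row in df.itertuples(index=False)
    ]
    return group_by_frame(dets)


def write_tracker_error_csv(
    series: list[tuple[int, float]], path: str | Path
) -> None:
    """Write a per-frame error series as ``frame,error_px`` CSV."""
    df = pd.DataFrame(series, columns=["frame", "error_px"])
    df.to_csv(path, index=False, lineterminator="\n")


def write_frames(stack: np.ndarray, directory: str | Path) -> list[Path]:
    """Write an 8-bit grayscale stack as PNG files ``frame_0001.png``, ..."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(stack):
        p = directory / f"frame_{i + 1:04d}.png"
        iio.imwrite(p, np.asarray(img, dtype=np.uint8))
        paths.append(p)
    return paths


def read_frames(source: str | Path) -> np.ndarray:
    """Read a frame stack from a directory of PNGs or a multi-frame TIFF."""
    import imageio.v3 as iio

    source = Path(source)
    if source.is_dir():
        paths = sorted(source.glob("frame_*.png")) or sorted(source.glob("*.png"))
        if not paths:
            raise ParseError(f"no PNG frames found in {source}")
        return np.stack([iio.imread(p) for p in paths])
    stack = np.asarray(iio.imread(source))
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValidationError(f"expected a grayscale stack, got shape {stack.shape}")
    return stack
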