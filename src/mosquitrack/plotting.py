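"""Diagnostic plots: trajectory overlays and tracker-error curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .metrics import TrajectoryPair, tracker_error_series
from .track import Track


def plot_trajectories(
    tracks: list[Track],
    gt_tracks: list[Track] | None = None,
    arena_size: tuple[int, int] | None = None,
    ax=None,
):
    """Overlay estimated (solid) and ground-truth (dashed) trajectories.

    The y axis is inverted to match image coordinates (origin top-left).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6.4))
    for track in tracks:
        ax.plot(track.x, track.y, lw=1.2, label=f"track {track.track_id}")
        ax.plot(track.x[0], track.y[0], marker="o", ms=4, color="k")
    if gt_tracks:
        for gt in gt_tracks:
            ax.plot(gt.x, gt.y, ls="--", lw=0.8, color="gray")
    if arena_size:
        ax.set_xlim(0, arena_size[0])
        ax.set_ylim(0, arena_size[1])
    ax.invert_yaxis()
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_aspect("equal")
    if len(tracks) <= 10:
        ax.legend(fontsize=7)
    return ax


def plot_tracker_error(pairs: list[TrajectoryPair], labels=None, ax=None):
    """Per-frame Euclidean error curves, one line per individual."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for i, pair in enumerate(pairs):
        series = tracker_error_series(pair)
        if not series:
            continue
        frames, errors = zip(*series)
        label = labels[i] if labels else f"individual {i + 1}"
        ax.plot(frames, errors, lw=0.9, label=label)
    ax.set_xlabel("frame")
    ax.set_ylabel("tracker error (px)")
    ax.legend(fontsize=7)
    return ax
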