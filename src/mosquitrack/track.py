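"""The per-individual trajectory container shared by every pipeline stage.

A :class:`Track` is an identity-labelled, frame-ordered sequence of image
positions. Each point records its provenance: ``detected`` (came from a
detector) or ``interpolated`` (filled in afterwards by spline/linear
interpolation). Frames are 1-based throughout the package, matching how
video frames are usually counted in behavioural recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

PROVENANCE_DETECTED = "detected"
PROVENANCE_INTERPOLATED = "interpolated"

STATE_ACTIVE = "active"
STATE_CLOSED = "closed"


@dataclass
class Track:
    """An ordered trajectory of one individual.

    Parameters
    ----------
    track_id
        Positive integer identity label.
    frames
        Strictly increasing 1-based frame numbers, one per point.
    x, y
        Pixel coordinates (x along width, y along height, origin top-left,
        y increasing downward). Sub-pixel floats are allowed.
    interpolated
        Boolean mask, True where the point was interpolated rather than
        detected.
    state
        ``"active"`` while a linker may still extend the track, else
        ``"closed"``.
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]
    state: str = STATE_CLOSED

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.frames.shape, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = len(self.frames)
        if n == 0:
            raise ValidationError("a track needs at least one point")
        if not (len(self.x) == len(self.y) == len(self.interpolated) == n):
            raise ValidationError("track column lengths differ")
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValidationError("track frames must be strictly increasing")
        if self.track_id < 1:
            raise ValidationError("track_id must be a positive integer")
        if self.state not in (STATE_ACTIVE, STATE_CLOSED):
            raise ValidationError(f"unknown track state {self.state!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def provenance(self) -> list[str]:
        return [
            PROVENANCE_INTERPOLATED if flag else PROVENANCE_DETECTED
            for flag in self.interpolated
        ]

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions."""
        return np.column_stack([self.x, self.y])

    def detected_mask(self) -> np.ndarray:
        return ~self.interpolated

    def point_at(self, frame: int) -> tuple[float, float] | None:
        """Position at ``frame``, or None if the track has no such point."""
        idx = np.searchsorted(self.frames, frame)
        if idx < len(self.frames) and self.frames[idx] == frame:
            return float(self.x[idx]), float(self.y[idx])
        return None

    def copy(self, **overrides) -> "Track":
        kwargs = dict(
            track_id=self.track_id,
            frames=self.frames.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            interpolated=self.interpolated.copy(),
            state=self.state,
        )
        kwargs.update(overrides)
        return Track(**kwargs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Track):
            return NotImplemented
        return (
            self.track_id == other.track_id
            and np.array_equal(self.frames, other.frames)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.interpolated, other.interpolated)
        )
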