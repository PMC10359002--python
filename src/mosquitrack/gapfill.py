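"""Natural cubic-spline interpolation of missing track frames.

Detections drop out where an animal crosses background clutter or a light
reflection, leaving frame holes inside otherwise continuous tracks. Flight
paths are smooth at 60 fps, so a cubic spline through the detected points
recovers the missing positions well for short gaps. x(frame) and y(frame)
are interpolated independently.

The spline is the classical natural cubic interpolant: piecewise cubics
meeting with continuous first and second derivatives at every interior
knot and zero second derivative at the two end knots. The interior
second derivatives solve a tridiagonal linear system; with exactly two
knots the spline degenerates to the straight line through them.

Long gaps are a documented failure mode of spline interpolation — the
cubic can swing far from any plausible path — so gaps longer than
``max_spline_gap`` frames fall back to linear interpolation between the
bracketing detections. No extrapolation is ever performed outside the
track's detected frame range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .errors import (
    ExtrapolationError,
    InsufficientDataError,
    ValidationError,
)
from .track import Track

DEFAULT_MAX_SPLINE_GAP = 30  # frames; 0.5 s at 60 fps


@dataclass(frozen=True)
class CubicSpline1D:
    """A natural cubic spline v(t) over strictly increasing knots.

    On interval i the spline is
    ``v(t) = a[i] + b[i]*dt + c[i]*dt**2 + d[i]*dt**3`` with
    ``dt = t - knot_times[i]``.
    """

    knot_times: np.ndarray
    knot_values: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def __call__(self, t) -> np.ndarray | float:
        return evaluate_spline(self, t)


def fit_natural_cubic_spline(
    knot_times: np.ndarray, knot_values: np.ndarray
) -> CubicSpline1D:
    """Fit the natural cubic spline through ``(t, v)`` knots.

    The interior second derivatives M satisfy, for i = 1..n-2 with
    ``h[i] = t[i+1] - t[i]``:

        h[i-1]*M[i-1] + 2*(h[i-1]+h[i])*M[i] + h[i]*M[i+1]
            = 6*((v[i+1]-v[i])/h[i] - (v[i]-v[i-1])/h[i-1])

    with M[0] = M[n-1] = 0 (natural end conditions). Interval coefficients
    follow from M in the standard way.
    """
    t = np.asarray(knot_times, dtype=np.float64)
    v = np.asarray(knot_values, dtype=np.float64)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValidationError("knot_times and knot_values must be equal-length 1-D")
    n = len(t)
    if n < 2:
        raise ValidationError("need at least 2 knots")
    h = np.diff(t)
    if np.any(h <= 0):
        raise ValidationError("knot times must be strictly increasing")

    m = np.zeros(n)  # second derivatives at the knots
    if n > 2:
        # tridiagonal system for the n-2 interior second derivatives
        diag = 2.0 * (h[:-1] + h[1:])
        lower = h[1:-1]
        upper = h[1:-1]
        rhs = 6.0 * (np.diff(v[1:]) / h[1:] - np.diff(v[:-1]) / h[:-1])
        ab = np.zeros((3, n - 2))
        ab[0, 1:] = upper
        ab[1, :] = diag
        ab[2, :-1] = lower
        m[1:-1] = solve_banded((1, 1), ab, rhs)

    a = v[:-1].copy()
    b = np.diff(v) / h - h * (2.0 * m[:-1] + m[1:]) / 6.0
    c = m[:-1] / 2.0
    d = (m[1:] - m[:-1]) / (6.0 * h)
    return CubicSpline1D(knot_times=t, knot_values=v, a=a, b=b, c=c, d=d)


def evaluate_spline(spline: CubicSpline1D, t) -> np.ndarray | float:
    """Evaluate the spline inside its knot range; never extrapolates."""
    t_arr = np.asarray(t, dtype=np.float64)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    t0, t1 = spline.knot_times[0], spline.knot_times[-1]
    if np.any(t_arr < t0) or np.any(t_arr > t1):
        raise ExtrapolationError(
            f"query outside knot range [{t0}, {t1}]"
        )
    idx = np.clip(
        np.searchsorted(spline.knot_times, t_arr, side="right") - 1,
        0,
        len(spline.a) - 1,
    )
    dt = t_arr - spline.knot_times[idx]
    out = spline.a[idx] + dt * (
        spline.b[idx] + dt * (spline.c[idx] + dt * spline.d[idx])
    )
    return float(out[0]) if scalar else out


def fill_track_gaps(
    track: Track, max_spline_gap: int = DEFAULT_MAX_SPLINE_GAP
) -> Track:
    """Fill every missing frame between the first and last detected frames.

    Gaps of length <= ``max_spline_gap`` frames are filled by the natural
    cubic spline fitted to *all* of the track's detected points; longer
    gaps use linear interpolation between the two bracketing detections.
    Filled points are marked interpolated; detected points are never
    altered. Idempotent: a track without holes is returned unchanged.
    """
    det = track.detected_mask()
    det_frames = track.frames[det]
    if len(det_frames) < 2:
        raise InsufficientDataError(
            "gap filling needs at least 2 detected points"
        )
    first, last = int(det_frames[0]), int(det_frames[-1])
    full = np.arange(first, last + 1)
    missing = np.setdiff1d(full, track.frames)
    if len(missing) == 0:
        return track

    spline_x = fit_natural_cubic_spline(det_frames, track.x[det])
    spline_y = fit_natural_cubic_spline(det_frames, track.y[det])

    new_frames: list[int] = []
    new_x: list[float] = []
    new_y: list[float] = []
    for f in missing:
        # bracketing detected knots define the gap this frame belongs to
        right = int(np.searchsorted(det_frames, f))
        left = right - 1
        gap_len = int(det_frames[right]) - int(det_frames[left]) - 1
        if gap_len <= max_spline_gap:
            fx = evaluate_spline(spline_x, float(f))
            fy = evaluate_spline(spline_y, float(f))
        else:
            frac = (f - det_frames[left]) / (det_frames[right] - det_frames[left])
            fx = track.x[det][left] + frac * (track.x[det][right] - track.x[det][left])
            fy = track.y[det][left] + frac * (track.y[det][right] - track.y[det][left])
        new_frames.append(int(f))
        new_x.append(float(fx))
        new_y.append(float(fy))

    frames = np.concatenate([track.frames, new_frames])
    xs = np.concatenate([track.x, new_x])
    ys = np.concatenate([track.y, new_y])
    interp = np.concatenate([track.interpolated, np.ones(len(new_frames), bool)])
    order = np.argsort(frames)
    return Track(
        track_id=track.track_id,
        frames=frames[order],
        x=xs[order],
        y=ys[order],
        interpolated=interp[order],
        state=track.state,
    )
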