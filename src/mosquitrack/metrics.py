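"""Tolerance-accuracy evaluation of estimated trajectories.

An estimated track is scored against its ground-truth trajectory frame by
frame. The per-frame error is the Euclidean distance

    d_f = sqrt((p_f - x_f)**2 + (q_f - y_f)**2)

between the estimated centre (p_f, q_f) and the ground-truth centroid
(x_f, y_f). Three summary indicators are reported per individual:

* mean distance m1 = (1/n') * sum of d_f over the n' frames where an
  estimate exists;
* the sample standard deviation of those distances (combined across
  individuals as the degrees-of-freedom-weighted pooled SD);
* tolerance accuracy: the percentage of ground-truth frames where BOTH
  |p_f - x_f| < tol and |q_f - y_f| < tol (strict, default tol = 8 px).
  Frames with no estimate count as inaccurate, so filling trajectory gaps
  raises accuracy.

The 8-px default reflects that a mosquito is not a single-pixel object —
8 px is 1.25% of a 640-px frame width and 1.56% of a 512-px height, about
one body length — so centroid placement anywhere on the body is accepted.

Percentages are displayed at two decimals with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import PairingError, UndefinedMetricError, ValidationError
from .track import Track

DEFAULT_TOLERANCE_PX = 8.0


def round_percent(value: float, decimals: int = 2) -> float:
    """Round half-up at ``decimals`` places, as report tables print."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(f"{value:.{decimals + 4}f}").quantize(quantum, ROUND_HALF_UP))


@dataclass
class TrajectoryPair:
    """Frame-aligned estimated vs ground-truth positions of one individual.

    Alignment is over the ground-truth frame set; frames where the
    estimate is missing are recorded as NaN and excluded from distance
    statistics but counted as inaccurate by the accuracy operations.
    """

    frames: np.ndarray  # ground-truth frames, ascending
    est_x: np.ndarray  # NaN where missing
    est_y: np.ndarray
    gt_x: np.ndarray
    gt_y: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.frames)
        for arr in (self.est_x, self.est_y, self.gt_x, self.gt_y):
            if len(arr) != n:
                raise ValidationError("pair column lengths differ")
        if np.any(np.isnan(self.gt_x)) or np.any(np.isnan(self.gt_y)):
            raise ValidationError("ground truth must be defined at every frame")

    @property
    def n(self) -> int:
        """Total number of ground-truth frames."""
        return len(self.frames)

    @property
    def defined(self) -> np.ndarray:
        """Mask of frames where the estimate exists."""
        return ~(np.isnan(self.est_x) | np.isnan(self.est_y))

    @property
    def missing_frames(self) -> np.ndarray:
        return self.frames[~self.defined]


def pair_trajectories(est: Track, gt: Track) -> TrajectoryPair:
    """Align an estimated track with a ground-truth track by frame number."""
    if len(est) == 0 or len(gt) == 0:
        raise ValidationError("tracks must be non-empty")
    if not np.intersect1d(est.frames, gt.frames).size:
        raise PairingError(
            f"estimated frames [{est.frames[0]}..{est.frames[-1]}] share no "
            f"frames with ground truth [{gt.frames[0]}..{gt.frames[-1]}]"
        )
    est_x = np.full(len(gt), np.nan)
    est_y = np.full(len(gt), np.nan)
    idx_in_gt = np.searchsorted(gt.frames, est.frames)
    for k, gi in enumerate(idx_in_gt):
        if gi < len(gt) and gt.frames[gi] == est.frames[k]:
            est_x[gi] = est.x[k]
            est_y[gi] = est.y[k]
    return TrajectoryPair(
        frames=gt.frames.copy(),
        est_x=est_x,
        est_y=est_y,
        gt_x=gt.x.copy(),
        gt_y=gt.y.copy(),
    )


def _distances(pair: TrajectoryPair) -> np.ndarray:
    """d_f for every ground-truth frame; NaN where the estimate is missing."""
    return np.hypot(pair.est_x - pair.gt_x, pair.est_y - pair.gt_y)


def frame_distance(pair: TrajectoryPair, f: int) -> float:
    """Euclidean error d_f at one frame; errors if no estimate exists there."""
    idx = np.searchsorted(pair.frames, f)
    if idx >= pair.n or pair.frames[idx] != f:
        raise UndefinedMetricError(f"frame {f} not in the ground-truth range")
    if not pair.defined[idx]:
        raise UndefinedMetricError(f"no estimate at frame {f}")
    return float(
        np.hypot(pair.est_x[idx] - pair.gt_x[idx], pair.est_y[idx] - pair.gt_y[idx])
    )


def mean_distance(pair: TrajectoryPair) -> float:
    """Mean of d_f over frames with a defined estimate."""
    d = _distances(pair)
    defined = ~np.isnan(d)
    if not defined.any():
        raise UndefinedMetricError("no frames with a defined distance")
    return float(d[defined].mean())


def distance_std(pair: TrajectoryPair) -> float:
    """Sample SD (ddof=1) of d_f over defined frames."""
    d = _distances(pair)
    d = d[~np.isnan(d)]
    if len(d) < 2:
        raise UndefinedMetricError("need >= 2 defined distances for an SD")
    return float(d.std(ddof=1))


def frame_accuracy_flag(
    pair: TrajectoryPair, f: int, tol_px: float = DEFAULT_TOLERANCE_PX
) -> bool:
    """Is the estimate at frame ``f`` within tolerance on BOTH axes (strict)?

    A missing estimate is inaccurate by definition.
    """
    idx = np.searchsorted(pair.frames, f)
    if idx >= pair.n or pair.frames[idx] != f:
        raise UndefinedMetricError(f"frame {f} not in the ground-truth range")
    if not pair.defined[idx]:
        return False
    return bool(
        abs(pair.est_x[idx] - pair.gt_x[idx]) < tol_px
        and abs(pair.est_y[idx] - pair.gt_y[idx]) < tol_px
    )


def track_accuracy(
    pair: TrajectoryPair, tol_px: float = DEFAULT_TOLERANCE_PX
) -> float:
    """Tolerance accuracy in percent over ALL ground-truth frames."""
    ok = (
        pair.defined
        & (np.abs(pair.est_x - pair.gt_x) < tol_px)
        & (np.abs(pair.est_y - pair.gt_y) < tol_px)
    )
    return 100.0 * float(ok.sum()) / pair.n


def pooled_std(pairs: list[TrajectoryPair]) -> float:
    """Degrees-of-freedom-weighted pooled SD of per-frame distances.

    s_p = sqrt( sum_i (n_i' - 1) * s_i**2 / sum_i (n_i' - 1) ) where s_i is
    the sample SD of individual i's distances and n_i' its defined count.
    """
    num = 0.0
    den = 0.0
    for pair in pairs:
        d = _distances(pair)
        d = d[~np.isnan(d)]
        if len(d) < 2:
            continue
        num += (len(d) - 1) * float(d.var(ddof=1))
        den += len(d) - 1
    if den == 0:
        raise UndefinedMetricError("all pairs degenerate; pooled SD undefined")
    return float(np.sqrt(num / den))


def tracker_error_series(pair: TrajectoryPair) -> list[tuple[int, float]]:
    """Ordered (frame, d_f) over frames with a defined distance.

    This is exactly the per-frame error used by :func:`mean_distance`; it
    is what gets plotted as a tracker-error curve.
    """
    d = _distances(pair)
    defined = ~np.isnan(d)
    return [
        (int(f), float(e)) for f, e in zip(pair.frames[defined], d[defined])
    ]


def mean_of_accuracies(accuracies: list[float]) -> float:
    """Unweighted mean of per-individual accuracies, printed at 2 dp.

    This is the aggregation behind scenario-level "average accuracy"
    figures: each individual contributes equally, regardless of how many
    frames it was tracked for.
    """
    if not accuracies:
        raise UndefinedMetricError("no accuracies to average")
    return round_percent(float(np.mean(accuracies)))


@dataclass
class IndividualReport:
    """Per-individual evaluation summary."""

    individual: int
    flying: bool
    accuracy_pct: float
    mean_distance_px: float
    distance_sd_px: float | None
    n_frames: int
    n_missing: int
    tracker_error: list[tuple[int, float]] = field(repr=False, default_factory=list)


@dataclass
class MetricReport:
    """Scenario-level evaluation report."""

    individuals: list[IndividualReport]
    tolerance_px: float
    mean_distance_px: float  # frame-pooled over all individuals
    per_individual_mean_distance_px: float  # mean of per-individual means
    pooled_sd: float | None
    flying_mean_accuracy_pct: float | None
    overall_mean_accuracy_pct: float

    def to_dict(self) -> dict:
        return {
            "tolerance_px": self.tolerance_px,
            "mean_distance_px": self.mean_distance_px,
            "per_individual_mean_distance_px": self.per_individual_mean_distance_px,
            "pooled_sd": self.pooled_sd,
            "flying_mean_accuracy_pct": self.flying_mean_accuracy_pct,
            "overall_mean_accuracy_pct": self.overall_mean_accuracy_pct,
            "individuals": [
                {
                    "individual": r.individual,
                    "flying": r.flying,
                    "accuracy_pct": r.accuracy_pct,
                    "mean_distance_px": r.mean_distance_px,
                    "distance_sd_px": r.distance_sd_px,
                    "n_frames": r.n_frames,
                    "n_missing": r.n_missing,
                }
                for r in self.individuals
            ],
        }

    def to_table(self) -> str:
        """Aligned plain-text table of the per-individual indicators."""
        header = (
            f"{'ind':>4} {'flying':>6} {'frames':>7} {'missing':>7} "
            f"{'mean_d(px)':>11} {'sd(px)':>8} {'accuracy%':>10}"
        )
        lines = [header, "-" * len(header)]
        for r in self.individuals:
            sd = f"{r.distance_sd_px:8.3f}" if r.distance_sd_px is not None else "     n/a"
            lines.append(
                f"{r.individual:>4} {str(r.flying):>6} {r.n_frames:>7} "
                f"{r.n_missing:>7} {r.mean_distance_px:11.3f} {sd} "
                f"{r.accuracy_pct:10.2f}"
            )
        lines.append("-" * len(header))
        pooled = f"{self.pooled_sd:.3f}" if self.pooled_sd is not None else "n/a"
        flying = (
            f"{self.flying_mean_accuracy_pct:.2f}%"
            if self.flying_mean_accuracy_pct is not None
            else "n/a"
        )
        lines.append(
            f"mean distance (frame-pooled): {self.mean_distance_px:.3f} px | "
            f"pooled SD: {pooled} | flying mean accuracy: {flying} | "
            f"overall mean accuracy: {self.overall_mean_accuracy_pct:.2f}% | "
            f"tolerance: {self.tolerance_px:g} px"
        )
        return "\n".join(lines)


def scenario_report(
    pairs: list[TrajectoryPair],
    flying_flags: list[bool],
    tol_px: float = DEFAULT_TOLERANCE_PX,
) -> MetricReport:
    """Aggregate per-individual indicators into a scenario report.

    The scenario mean distance pools d_f over every individual's defined
    frames; the per-individual-mean variant is also reported. Accuracy
    aggregates are unweighted means over individuals: one over the flying
    individuals only, one over all individuals.
    """
    if not pairs:
        raise UndefinedMetricError("scenario_report needs at least one pair")
    if len(flying_flags) != len(pairs):
        raise ValidationError("flying_flags length must match pairs")

    individuals: list[IndividualReport] = []
    all_distances: list[np.ndarray] = []
    for i, pair in enumerate(pairs):
        d = _distances(pair)
        defined = ~np.isnan(d)
        dd = d[defined]
        all_distances.append(dd)
        individuals.append(
            IndividualReport(
                individual=i + 1,
                flying=bool(flying_flags[i]),
                accuracy_pct=round_percent(track_accuracy(pair, tol_px)),
                mean_distance_px=float(dd.mean()) if len(dd) else float("nan"),
                distance_sd_px=float(dd.std(ddof=1)) if len(dd) > 1 else None,
                n_frames=pair.n,
                n_missing=int((~defined).sum()),
                tracker_error=tracker_error_series(pair),
            )
        )

    pooled = np.concatenate(all_distances) if all_distances else np.array([])
    try:
        pooled_sd = pooled_std(pairs)
    except UndefinedMetricError:
        pooled_sd = None

    flying_acc = [r.accuracy_pct for r in individuals if r.flying]
    return MetricReport(
        individuals=individuals,
        tolerance_px=tol_px,
        mean_distance_px=float(pooled.mean()) if len(pooled) else float("nan"),
        per_individual_mean_distance_px=float(
            np.mean([r.mean_distance_px for r in individuals])
        ),
        pooled_sd=pooled_sd,
        flying_mean_accuracy_pct=(
            mean_of_accuracies(flying_acc) if flying_acc else None
        ),
        overall_mean_accuracy_pct=mean_of_accuracies(
            [r.accuracy_pct for r in individuals]
        ),
    )
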