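"""Tracking-error metrics, time normalization, and trial/subject aggregation.

The tracking error between the reference joint angle x1 and the estimated
(exoskeleton) angle x2 is summarized by

    absolute error  Delta = |x2 - x1|                 (degrees)
    relative error  delta = |x2 - x1| / x1 * 100      (percent)

evaluated on a common time grid.  Because the trial starts near 0 deg, the
relative error is computed only over a late evaluation window (1-5 s by
default) where the denominator is well away from zero.  Error curves are
reported on movement time normalized to 0-100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .signal_core import AngleTrajectory

__all__ = [
    "TrackingResult",
    "ErrorSummary",
    "align",
    "absolute_error",
    "relative_error",
    "evaluation_window",
    "normalize_time",
    "summarize",
]

#: Relative error is restricted to this window (seconds) by default.
DEFAULT_REL_WINDOW: tuple[float, float] = (1.0, 5.0)


@dataclass(frozen=True)
class TrackingResult:
    """Reference and estimate resampled onto a common time grid."""

    reference: AngleTrajectory
    estimate: AngleTrajectory
    grid: np.ndarray
    ref_on_grid: np.ndarray
    est_on_grid: np.ndarray

    def __post_init__(self) -> None:
        if self.reference.convention != self.estimate.convention:
            raise ValueError("reference and estimate must share a convention")
        if self.grid.size == 0:
            raise ValueError("empty alignment grid")


def align(reference: AngleTrajectory, estimate: AngleTrajectory) -> TrackingResult:
    """Resample both trajectories to their overlapping reference grid.

    The common grid is the reference's own timestamps (the angle-sensor
    rate), restricted to the interval where the estimate has support; both
    signals are linearly interpolated onto it.
    """
    t0 = max(reference.timestamps[0], estimate.timestamps[0])
    t1 = min(reference.timestamps[-1], estimate.timestamps[-1])
    mask = (reference.timestamps >= t0) & (reference.timestamps <= t1)
    grid = reference.timestamps[mask]
    if grid.size == 0:
        raise ValueError("trajectories do not overlap in time")
    ref = reference.angles[mask]
    est = np.interp(grid, estimate.timestamps, estimate.angles)
    return TrackingResult(reference, estimate, grid, ref, est)


def absolute_error(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Elementwise |x2 - x1| in degrees."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("misaligned lengths")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("inputs must be finite")
    return np.abs(x2 - x1)


def relative_error(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Elementwise |x2 - x1| / x1 * 100, in percent.

    The reference must be nonzero at every evaluated sample; callers enforce
    this by restricting to an evaluation window first.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("misaligned lengths")
    if np.any(x1 == 0):
        raise ValueError(
            "reference angle is zero inside the evaluation window; "
            "restrict the window to exclude it"
        )
    return np.abs(x2 - x1) / np.abs(x1) * 100.0


def evaluation_window(
    result: TrackingResult, t_start: float, t_end: float
) -> TrackingResult:
    """Restrict an aligned result to [t_start, t_end] seconds."""
    mask = (result.grid >= t_start) & (result.grid <= t_end)
    if not np.any(mask):
        raise ValueError(f"evaluation window [{t_start}, {t_end}] s is empty")
    return TrackingResult(
        result.reference,
        result.estimate,
        result.grid[mask],
        result.ref_on_grid[mask],
        result.est_on_grid[mask],
    )


def normalize_time(
    timestamps: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map timestamps affinely onto [0, 100]% of movement time.

    Values are passed through untouched; idempotent on already-normalized
    input.
    """
    ts = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    if ts.size != values.size:
        raise ValueError("timestamps and values must have equal length")
    if ts.size < 2:
        raise ValueError("cannot normalize a single-point curve")
    span = ts[-1] - ts[0]
    if span <= 0:
        raise ValueError("timestamps must span a positive interval")
    return (ts - ts[0]) / span * 100.0, values


@dataclass(frozen=True)
class ErrorSummary:
    """Aggregated tracking-error metrics.

    ``mean_abs_error`` (deg) and ``mean_rel_error`` (%) average trials
    within each subject first, then subjects.  ``sd_error`` (deg) is the
    standard deviation of the signed error pooled over time, trials, and
    subjects.  The curves give the mean absolute error versus normalized
    movement time (0-100%).
    """

    mean_abs_error: float
    sd_error: float
    mean_rel_error: float
    curve_pct: np.ndarray
    curve_abs_error: np.ndarray
    n_subjects: int
    n_trials: int
    n_samples: int


GroupedResults = Union[
    Sequence[TrackingResult], Sequence[Sequence[TrackingResult]]
]


def summarize(
    results: GroupedResults,
    rel_window: tuple[float, float] = DEFAULT_REL_WINDOW,
    n_curve: int = 101,
) -> ErrorSummary:
    """Aggregate tracking results into an :class:`ErrorSummary`.

    ``results`` is either a flat sequence of :class:`TrackingResult` (treated
    as one subject) or a sequence of per-subject sequences.  Per-trial means
    are averaged over trials, then over subjects; the absolute error uses the
    full trial, the relative error only the ``rel_window``.  Invariant to
    trial ordering.
    """
    if len(results) == 0:
        raise ValueError("cannot summarize an empty collection")
    if isinstance(results[0], TrackingResult):
        groups: Sequence[Sequence[TrackingResult]] = [results]  # type: ignore[list-item]
    else:
        groups = results  # type: ignore[assignment]

    curve_grid = np.linspace(0.0, 100.0, n_curve)
    subject_abs, subject_rel = [], []
    pooled_signed: list[np.ndarray] = []
    curves = []
    n_trials = 0
    for group in groups:
        if len(group) == 0:
            raise ValueError("subject group with no trials")
        trial_abs, trial_rel = [], []
        for res in group:
            n_trials += 1
            abs_err = absolute_error(res.ref_on_grid, res.est_on_grid)
            trial_abs.append(float(np.mean(abs_err)))
            windowed = evaluation_window(res, *rel_window)
            rel_err = relative_error(windowed.ref_on_grid, windowed.est_on_grid)
            trial_rel.append(float(np.mean(rel_err)))
            pooled_signed.append(res.est_on_grid - res.ref_on_grid)
            pct, vals = normalize_time(res.grid, abs_err)
            curves.append(np.interp(curve_grid, pct, vals))
        subject_abs.append(float(np.mean(trial_abs)))
        subject_rel.append(float(np.mean(trial_rel)))
    signed = np.concatenate(pooled_signed)
    return ErrorSummary(
        mean_abs_error=float(np.mean(subject_abs)),
        sd_error=float(np.std(signed)),
        mean_rel_error=float(np.mean(subject_rel)),
        curve_pct=curve_grid,
        curve_abs_error=np.mean(curves, axis=0),
        n_subjects=len(groups),
        n_trials=n_trials,
        n_samples=signed.size,
    )
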