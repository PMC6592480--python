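"""Signal processing: from a raw minute trace to the regression minutes.

The chain is: centered moving-average smoothing of both heart rate and
activity within each contiguous wear segment, selection of minutes where
both smoothed signals increased from the previous minute (co-increase),
then a heart-rate gate keeping only minutes above a threshold (default
120 beats/min, where the HR-activity relationship is approximately linear).
A trace is usable only if it carries at least ``min_wear_minutes`` (default
900 = 15 hours) of valid wear time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError
from .io import ActivityTrace

DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_HR_GATE = 120.0
DEFAULT_MIN_WEAR_MINUTES = 900
MIN_SPAN_DAYS = 3


@dataclass
class SelectionResult:
    """Indices retained by the selection chain, with per-stage counts.

    ``selected_idx`` are positions into the trace arrays; every retained
    minute lies in a wear segment and has smoothed heart rate strictly above
    ``hr_threshold``. Counts are monotone non-increasing along the chain.
    """

    selected_idx: np.ndarray
    n_wear_minutes: int
    n_coincrease: int
    n_after_hr_gate: int
    hr_threshold: float

    def __post_init__(self):
        self.selected_idx = np.asarray(self.selected_idx, dtype=int)
        if not (self.n_after_hr_gate <= self.n_coincrease <= self.n_wear_minutes):
            raise DataError("selection counts must be monotone non-increasing")


@dataclass
class SufficiencyResult:
    """Outcome of the wear-time sufficiency check."""

    passed: bool
    n_wear_minutes: int
    required_minutes: int
    span_days: float
    warnings: list = field(default_factory=list)


def wear_segments(trace: ActivityTrace) -> list[np.ndarray]:
    """Contiguous wear segments: runs of worn minutes at consecutive timestamps.

    Differences (and smoothing windows) never cross a segment boundary, so a
    step across a non-wear gap can never be selected.
    """
    mask = trace.wear_mask
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    t = trace.timestamps.asi8
    # break where indices are non-adjacent or timestamps jump by more than one minute
    gap = np.diff(idx) != 1
    jump = (t[idx[1:]] - t[idx[:-1]]) != 60_000_000_000
    breaks = np.flatnonzero(gap | jump) + 1
    return np.split(idx, breaks)


def smooth(values, window: int = DEFAULT_SMOOTH_WINDOW, segments=None) -> np.ndarray:
    """Centered moving average with a shrinking window at segment edges.

    ``segments`` is a list of index arrays (from :func:`wear_segments`); when
    omitted the whole array is one segment. Missing values stay missing.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    if segments is None:
        segments = [np.arange(len(values))]
    for seg in segments:
        if len(seg) == 0:
            continue
        s = pd.Series(values[seg])
        out[seg] = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return out


def select_coincrease(hr, aee, segments=None) -> np.ndarray:
    """Minutes where both signals increased from the previous minute.

    Returns the later endpoint of each qualifying step, within contiguous
    segments only. Strict inequality: a flat step never qualifies.
    """
    hr = np.asarray(hr, dtype=float)
    aee = np.asarray(aee, dtype=float)
    if len(hr) != len(aee):
        raise DataError("hr and aee length mismatch")
    if segments is None:
        segments = [np.arange(len(hr))]
    picked = []
    for seg in segments:
        if len(seg) < 2:
            continue
        dhr = np.diff(hr[seg])
        daee = np.diff(aee[seg])
        good = (dhr > 0) & (daee > 0)
        picked.append(seg[1:][good])
    if not picked:
        return np.array([], dtype=int)
    return np.concatenate(picked)


def apply_hr_gate(idx, hr, threshold: float = DEFAULT_HR_GATE) -> np.ndarray:
    """Keep only indices whose heart rate is strictly above ``threshold``."""
    if threshold <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    idx = np.asarray(idx, dtype=int)
    hr = np.asarray(hr, dtype=float)
    if idx.size == 0:
        return idx
    return idx[hr[idx] > threshold]


def select_activity_minutes(
    trace: ActivityTrace,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    hr_gate: float = DEFAULT_HR_GATE,
) -> tuple[SelectionResult, np.ndarray, np.ndarray]:
    """Run the full chain; returns the selection plus both smoothed series."""
    segs = wear_segments(trace)
    hr_s = smooth(trace.hr, smooth_window, segs)
    aee_s = smooth(trace.aee, smooth_window, segs)
    co_idx = select_coincrease(hr_s, aee_s, segs)
    gated = apply_hr_gate(co_idx, hr_s, hr_gate)
    sel = SelectionResult(
        selected_idx=gated,
        n_wear_minutes=trace.n_wear_minutes,
        n_coincrease=int(co_idx.size),
        n_after_hr_gate=int(gated.size),
        hr_threshold=float(hr_gate),
    )
    return sel, hr_s, aee_s


def check_sufficiency(
    trace: ActivityTrace, min_minutes: int = DEFAULT_MIN_WEAR_MINUTES
) -> SufficiencyResult:
    """Pass iff total valid wear time is at least ``min_minutes`` (default 15 h).

    A calendar span under 3 days yields a warning, not a failure.
    """
    if min_minutes < 0:
        raise ParameterError("min_minutes must be nonnegative")
    n_wear = trace.n_wear_minutes
    span = (trace.timestamps[-1] - trace.timestamps[0]).total_seconds() / 86400.0
    warnings = []
    if span < MIN_SPAN_DAYS:
        warnings.append(
            f"trace spans {span:.2f} days; {MIN_SPAN_DAYS} consecutive days recommended"
        )
    return SufficiencyResult(
        passed=n_wear >= min_minutes,
        n_wear_minutes=n_wear,
        required_minutes=int(min_minutes),
        span_days=span,
        warnings=warnings,
    )
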