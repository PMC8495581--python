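"""Tolerance classification of strides and per-walk step counting.

Accuracy compares the stride's summed peak load — as a percent of the
ideal total load — with the inclusive correct window (95–105 % at the
default tolerance).  Balance compares the left/right peak difference
with the balance limit.  Simultaneity and fluency come from the stride's
onset lag and intra-support peak counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .core import (
    AccuracyStatus,
    GaitMode,
    SessionConfig,
    balance_limit,
    percent_of_ideal,
    percent_window,
)
from .detection import Stride


class BalanceStatus(str, enum.Enum):
    BALANCED = "balanced"
    IMBALANCED = "imbalanced"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class ClassifiedStride:
    stride: Stride
    pct: float
    accuracy: AccuracyStatus
    balance: BalanceStatus
    simultaneous: bool
    fluent: bool

    @property
    def is_error(self) -> bool:
        """True when the stride's load accuracy is wrong (over or under)."""
        return self.accuracy is not AccuracyStatus.CORRECT


@dataclass
class WalkCounters:
    """Per-walk tallies; accuracy statuses partition the strides."""

    n_strides: int = 0
    n_correct: int = 0
    n_overload: int = 0
    n_underload: int = 0
    n_balance_errors: int = 0
    n_simultaneity_errors: int = 0
    n_fluency_errors: int = 0

    @property
    def n_errors(self) -> int:
        return self.n_overload + self.n_underload


def classify_accuracy(pct: float, config: SessionConfig) -> AccuracyStatus:
    """Classify a percent-of-ideal peak load against the inclusive window.

    Bounds are inclusive: at the default tolerance, 95.00 and 105.00 are
    both correct; values outside are overload (above) or underload
    (below).
    """
    if pct < 0:
        raise ValueError(f"percent must be >= 0, got {pct}")
    lower, upper = percent_window(config)
    if pct > upper:
        return AccuracyStatus.OVERLOAD
    if pct < lower:
        return AccuracyStatus.UNDERLOAD
    return AccuracyStatus.CORRECT


def classify_balance(left_peak: float | None, right_peak: float | None,
                     config: SessionConfig) -> BalanceStatus:
    """Compare the left/right peak difference with the balance limit.

    The limit is inclusive: a difference exactly at the limit is
    balanced.  In unilateral gait balance is not applicable; in bilateral
    gait a missing side is an imbalance by definition.
    """
    if config.gait_mode is not GaitMode.BILATERAL:
        return BalanceStatus.NOT_APPLICABLE
    if left_peak is None or right_peak is None:
        return BalanceStatus.IMBALANCED
    if abs(left_peak - right_peak) <= balance_limit(config):
        return BalanceStatus.BALANCED
    return BalanceStatus.IMBALANCED


def classify_stride(stride: Stride, config: SessionConfig) -> ClassifiedStride:
    """Full classification of one stride.

    * accuracy — from the summed peak as percent of ideal;
    * balance — from the per-side peaks (bilateral only);
    * simultaneous — both sides present and onset lag within the
      simultaneity window;
    * fluent — every constituent support shows a single prominent peak.

    A single-sided stride in bilateral mode is non-simultaneous and
    imbalanced, but its accuracy is still computed from the available
    total (the step counter counts every crutch support).
    """
    pct = percent_of_ideal(stride.total_peak, config)
    accuracy = classify_accuracy(pct, config)
    left_peak = stride.left.peak if stride.left is not None else None
    right_peak = stride.right.peak if stride.right is not None else None
    balance = classify_balance(left_peak, right_peak, config)
    if config.gait_mode is GaitMode.BILATERAL:
        simultaneous = (stride.both_sides and stride.onset_lag is not None
                        and stride.onset_lag <= config.simultaneity_window)
    else:
        simultaneous = True
    fluent = all(s.n_prominent_peaks == 1
                 for s in (stride.left, stride.right) if s is not None)
    return ClassifiedStride(stride, pct, accuracy, balance, simultaneous, fluent)


def count_walk(classified: list[ClassifiedStride]) -> WalkCounters:
    """Tally a walk's strides by accuracy, balance, simultaneity, fluency."""
    c = WalkCounters(n_strides=len(classified))
    for cs in classified:
        if cs.accuracy is AccuracyStatus.CORRECT:
            c.n_correct += 1
        elif cs.accuracy is AccuracyStatus.OVERLOAD:
            c.n_overload += 1
        else:
            c.n_underload += 1
        if cs.balance is BalanceStatus.IMBALANCED:
            c.n_balance_errors += 1
        if not cs.simultaneous:
            c.n_simultaneity_errors += 1
        if not cs.fluent:
            c.n_fluency_errors += 1
    return c


def classify_percents(percents, config: SessionConfig) -> list[AccuracyStatus]:
    """Classify a sequence of percent-of-ideal values (fixture path)."""
    return [classify_accuracy(p, config) for p in percents]
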