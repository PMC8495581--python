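"""Segmentation of crutch force signals into supports and strides.

A *support* is one stance phase of a crutch: the interval from the
instant the force rises through the onset threshold until it falls back
below the release threshold.  Detection uses hysteresis (release at half
the onset threshold) so noise near the threshold cannot split a support,
and discards excursions shorter than the configured minimum duration.

Bilateral strides are formed by greedily pairing left and right supports
by onset proximity; a support left unpaired becomes a single-sided stride
and counts as a simultaneity violation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import SessionConfig
from .signal_io import ForceSeries

#: release threshold as a fraction of the onset threshold (hysteresis)
RELEASE_FRACTION = 0.5

#: default prominence threshold for intra-support fluctuation peaks,
#: as a fraction of the support's maximum load
DEFAULT_PROMINENCE_FRACTION = 0.10


@dataclass
class Support:
    """One detected crutch stance interval."""

    side: str
    onset: float          # ms, first sample at/above the onset threshold
    offset: float         # ms, last sample before force falls below release
    peak: float           # kgf, maximum load within the interval
    peak_time: float      # ms, earliest time attaining the peak
    n_prominent_peaks: int = 1
    saturated: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Stride:
    """A paired left/right support (bilateral) or a lone support (unilateral)."""

    index: int
    left: Support | None
    right: Support | None
    onset_lag: float | None = None   # ms, |left.onset - right.onset| when both present

    @property
    def total_peak(self) -> float:
        total = 0.0
        if self.left is not None:
            total += self.left.peak
        if self.right is not None:
            total += self.right.peak
        return total

    @property
    def onset(self) -> float:
        onsets = [s.onset for s in (self.left, self.right) if s is not None]
        return min(onsets)

    @property
    def offset(self) -> float:
        offsets = [s.offset for s in (self.left, self.right) if s is not None]
        return max(offsets)

    @property
    def both_sides(self) -> bool:
        return self.left is not None and self.right is not None


def detect_supports(series: ForceSeries, config: SessionConfig,
                    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION
                    ) -> list[Support]:
    """Segment a force series into time-ordered, disjoint supports.

    A support opens when the force rises to or above the onset threshold
    and closes when it falls below ``RELEASE_FRACTION`` times that
    threshold; intervals shorter than ``config.min_support_duration`` are
    discarded.  Each support carries its peak load (earliest sample at
    ties) and the number of prominent intra-support peaks.
    """
    if len(series) == 0:
        return []
    if not series.is_uniform():
        raise ValueError("support detection requires uniform sampling")
    onset_thr = config.effective_onset_threshold
    release_thr = RELEASE_FRACTION * onset_thr
    f = series.force_kgf
    t = series.time_ms

    supports: list[Support] = []
    start: int | None = None
    for i in range(len(f)):
        if start is None:
            if f[i] >= onset_thr:
                start = i
        else:
            if f[i] < release_thr:
                _maybe_append(supports, series, start, i - 1, config, prominence_fraction)
                start = None
    if start is not None:
        _maybe_append(supports, series, start, len(f) - 1, config, prominence_fraction)
    return supports


def _maybe_append(supports: list[Support], series: ForceSeries, i0: int, i1: int,
                  config: SessionConfig, prominence_fraction: float) -> None:
    t = series.time_ms
    if t[i1] - t[i0] < config.min_support_duration:
        return
    seg = series.force_kgf[i0:i1 + 1]
    k = int(np.argmax(seg))          # argmax returns the earliest maximum
    sup = Support(
        side=series.side,
        onset=float(t[i0]),
        offset=float(t[i1]),
        peak=float(seg[k]),
        peak_time=float(t[i0 + k]),
    )
    sup.n_prominent_peaks = _count_prominent(seg, prominence_fraction)
    supports.append(sup)


def peak_load(support: Support, series: ForceSeries) -> tuple[float, float]:
    """Maximum load (kgf) and its time (ms) within a support's interval.

    Ties resolve to the earliest sample.
    """
    mask = (series.time_ms >= support.onset) & (series.time_ms <= support.offset)
    if not mask.any():
        raise ValueError("support interval contains no samples of this series")
    seg = series.force_kgf[mask]
    tt = series.time_ms[mask]
    k = int(np.argmax(seg))
    return float(seg[k]), float(tt[k])


def _count_prominent(segment: np.ndarray, prominence_fraction: float) -> int:
    if not 0 < prominence_fraction < 1:
        raise ValueError("prominence_fraction must be in (0, 1)")
    if len(segment) < 3:
        return 1
    prominence = prominence_fraction * float(segment.max())
    peaks, _ = find_peaks(segment, prominence=prominence)
    return max(1, len(peaks))


def count_prominent_peaks(support: Support, series: ForceSeries,
                          prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION
                          ) -> int:
    """Number of prominent local maxima within a support.

    A smooth single-hump support yields 1; a second peak counts only if
    the trough separating it sits at least ``prominence_fraction`` of the
    support's maximum below the smaller neighbouring maximum.  More than
    one prominent peak marks the support as non-fluent (hesitant loading).
    """
    mask = (series.time_ms >= support.onset) & (series.time_ms <= support.offset)
    return _count_prominent(series.force_kgf[mask], prominence_fraction)


def pair_supports(left_supports: list[Support], right_supports: list[Support],
                  config: SessionConfig) -> list[Stride]:
    """Pair left and right supports into strides by onset proximity.

    Greedy 1:1 matching: candidate pairs are ranked by absolute onset
    lag and accepted while the lag does not exceed the pairing horizon
    (one cadence period, estimated as the median inter-onset interval of
    either side; unbounded when a side has fewer than two supports).
    Unpaired supports become single-sided strides.  Strides are returned
    time-ordered with 1-based indices.
    """
    horizon = _pairing_horizon(left_supports, right_supports)
    candidates = sorted(
        ((abs(ls.onset - rs.onset), i, j)
         for i, ls in enumerate(left_supports)
         for j, rs in enumerate(right_supports)),
        key=lambda c: (c[0], c[1], c[2]),
    )
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[Support, Support]] = []
    for lag, i, j in candidates:
        if lag > horizon:
            break
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        pairs.append((left_supports[i], right_supports[j]))

    strides: list[Stride] = []
    for ls, rs in pairs:
        strides.append(Stride(0, ls, rs, onset_lag=abs(ls.onset - rs.onset)))
    strides.extend(Stride(0, ls, None) for i, ls in enumerate(left_supports) if i not in used_l)
    strides.extend(Stride(0, None, rs) for j, rs in enumerate(right_supports) if j not in used_r)
    strides.sort(key=lambda s: s.onset)
    for k, s in enumerate(strides, start=1):
        s.index = k
    return strides


def _pairing_horizon(left: list[Support], right: list[Support]) -> float:
    for side in (left, right):
        if len(side) >= 2:
            onsets = np.array([s.onset for s in side])
            return float(np.median(np.diff(onsets)))
    return float("inf")
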