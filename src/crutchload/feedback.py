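"""Feedback event generation: bar colour states and terminal beeps.

Three display modes exist.  *Double* shows one vertical bar per crutch
against the per-crutch tolerance window, *single* shows the summed load
against the total window, and *balance* shows a horizontal bar encoding
the signed left/right difference relative to the balance limit.  A bar
is green while the displayed load behaves, red while the mode's error
condition holds.

Colour rules reconcile continuous concurrent feedback with terminal
correctness: an over-window load turns red the instant it exceeds the
upper guide line and stays red until the support ends, whereas an
underload can only be confirmed once the support is over — the rising
and falling signal is always briefly below the window — so it is
revealed as a 300 ms red flash immediately after the support.

Each erroneous stride additionally emits one 300 ms terminal beep at
the later support offset: high-pitched for crutch underload (the
affected limb was overloaded, the clinically risky direction) and
standard for crutch overload.  In balance mode, each maximal episode of
limit violation during simultaneous loading emits one beep instead.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core import (
    AccuracyStatus,
    GaitMode,
    NotApplicableError,
    SessionConfig,
    WindowScope,
    balance_limit,
    tolerance_window,
)
from .classify import ClassifiedStride
from .signal_io import ForceSeries

BEEP_DURATION_MS = 300.0


class DisplayMode(str, enum.Enum):
    DOUBLE = "double"
    SINGLE = "single"
    BALANCE = "balance"


class Tone(str, enum.Enum):
    HIGH = "high"
    STANDARD = "standard"


class BeepCause(str, enum.Enum):
    UNDERLOAD_CRUTCHES = "underload_crutches"
    OVERLOAD_CRUTCHES = "overload_crutches"
    IMBALANCE = "imbalance"


@dataclass
class BarState:
    time: float                      # ms
    mode: DisplayMode
    left_value: float | None
    right_value: float | None
    total_value: float
    color: str                       # "green" | "red"
    balance_position: float | None   # signed (left-right)/limit in [-1, 1], balance mode
    guide_ideal: float
    guide_lower: float
    guide_upper: float


@dataclass
class BeepEvent:
    time: float                      # ms, beep onset
    tone: Tone
    cause: BeepCause
    duration: float = BEEP_DURATION_MS


def terminal_events(classified: ClassifiedStride, config: SessionConfig) -> list[BeepEvent]:
    """Beep(s) for one stride in double/single mode: one per wrong stride.

    Emitted at the later support offset.  Crutch underload means the
    affected limb took too much weight, so it gets the high-pitched
    (most annoying) tone; crutch overload gets the standard tone.
    Correct strides are silent.
    """
    if classified.accuracy is AccuracyStatus.CORRECT:
        return []
    t = classified.stride.offset
    if classified.accuracy is AccuracyStatus.UNDERLOAD:
        return [BeepEvent(time=t, tone=Tone.HIGH, cause=BeepCause.UNDERLOAD_CRUTCHES)]
    return [BeepEvent(time=t, tone=Tone.STANDARD, cause=BeepCause.OVERLOAD_CRUTCHES)]


def _support_intervals(classified: list[ClassifiedStride]):
    """(onset, offset, peak_below_lower) per constituent support."""
    out = []
    for cs in classified:
        for sup in (cs.stride.left, cs.stride.right):
            if sup is not None:
                out.append((sup.onset, sup.offset, sup.peak, sup.side))
    return out


def concurrent_bar_stream(left: ForceSeries, right: ForceSeries,
                          classified: list[ClassifiedStride],
                          mode: DisplayMode | str,
                          config: SessionConfig) -> list[BarState]:
    """One :class:`BarState` per sample instant for the chosen display mode.

    Double/single: red from the instant the displayed value exceeds the
    upper guide line until the support ends, and red for the 300 ms
    after a support whose peak ended below the lower line.  Balance: red
    whenever the left/right difference exceeds the balance limit while
    both crutches are loaded.
    """
    mode = DisplayMode(mode)
    if mode is DisplayMode.BALANCE and config.gait_mode is not GaitMode.BILATERAL:
        raise NotApplicableError(
            "balance display is meaningless in unilateral assisted gait"
        )
    if not np.array_equal(left.time_ms, right.time_ms):
        raise ValueError("left and right series must share a time base")
    t = left.time_ms
    lf, rf = left.force_kgf, right.force_kgf
    total = lf + rf

    if mode is DisplayMode.BALANCE:
        return _balance_stream(t, lf, rf, config)

    scope = WindowScope.PER_CRUTCH if mode is DisplayMode.DOUBLE else WindowScope.TOTAL
    win = tolerance_window(config, scope)

    red = np.zeros(len(t), dtype=bool)
    supports = _support_intervals(classified)
    for onset, offset, peak, side in supports:
        in_sup = (t >= onset) & (t <= offset)
        if mode is DisplayMode.SINGLE:
            shown = total
        else:
            shown = lf if side == "left" else rf
        over = in_sup & (shown > win.upper)
        if over.any():
            # sticky red: from first over-window instant until support end
            first = np.argmax(over)
            red |= in_sup & (np.arange(len(t)) >= first)
        if mode is DisplayMode.DOUBLE and peak < win.lower:
            red |= (t > offset) & (t <= offset + BEEP_DURATION_MS)

    if mode is DisplayMode.SINGLE:
        # terminal underload reveal driven by the stride's summed peak
        for cs in classified:
            if cs.stride.total_peak < win.lower:
                off = cs.stride.offset
                red |= (t > off) & (t <= off + BEEP_DURATION_MS)

    states = []
    for i in range(len(t)):
        states.append(BarState(
            time=float(t[i]), mode=mode,
            left_value=float(lf[i]) if mode is DisplayMode.DOUBLE else None,
            right_value=float(rf[i]) if mode is DisplayMode.DOUBLE else None,
            total_value=float(total[i]),
            color="red" if red[i] else "green",
            balance_position=None,
            guide_ideal=win.ideal, guide_lower=win.lower, guide_upper=win.upper,
        ))
    return states


def _balance_stream(t, lf, rf, config: SessionConfig) -> list[BarState]:
    limit = balance_limit(config)
    thr = config.effective_onset_threshold
    both_loaded = (lf >= thr) & (rf >= thr)
    diff = lf - rf
    violating = both_loaded & (np.abs(diff) > limit)
    states = []
    for i in range(len(t)):
        if limit > 0:
            pos = float(np.clip(diff[i] / limit, -1.0, 1.0))
        else:
            pos = float(np.sign(diff[i]))
        states.append(BarState(
            time=float(t[i]), mode=DisplayMode.BALANCE,
            left_value=float(lf[i]), right_value=float(rf[i]),
            total_value=float(lf[i] + rf[i]),
            color="red" if violating[i] else "green",
            balance_position=pos,
            guide_ideal=0.0, guide_lower=-limit, guide_upper=limit,
        ))
    return states


def balance_episodes(left: ForceSeries, right: ForceSeries,
                     config: SessionConfig) -> list[tuple[float, float]]:
    """Maximal intervals of balance-limit violation during simultaneous loading."""
    limit = balance_limit(config)
    thr = config.effective_onset_threshold
    t = left.time_ms
    violating = ((left.force_kgf >= thr) & (right.force_kgf >= thr)
                 & (np.abs(left.force_kgf - right.force_kgf) > limit))
    episodes = []
    start = None
    for i, v in enumerate(violating):
        if v and start is None:
            start = t[i]
        elif not v and start is not None:
            episodes.append((float(start), float(t[i - 1])))
            start = None
    if start is not None:
        episodes.append((float(start), float(t[-1])))
    return episodes


def session_event_log(left: ForceSeries, right: ForceSeries,
                      classified: list[ClassifiedStride],
                      mode: DisplayMode | str,
                      config: SessionConfig) -> list[dict]:
    """Merged, strictly time-ordered stream of bar states and beeps.

    In double/single mode each erroneous stride beeps once; in balance
    mode each violation episode beeps once (at episode onset).  Events
    are plain dicts ready for JSON-lines serialization.
    """
    mode = DisplayMode(mode)
    events: list[dict] = []
    for bs in concurrent_bar_stream(left, right, classified, mode, config):
        d = asdict(bs)
        d["kind"] = "bar"
        d["mode"] = bs.mode.value
        events.append(d)
    if mode is DisplayMode.BALANCE:
        for start, _end in balance_episodes(left, right, config):
            events.append({
                "kind": "beep", "time": start,
                "duration": BEEP_DURATION_MS,
                "tone": Tone.STANDARD.value,
                "cause": BeepCause.IMBALANCE.value,
            })
    else:
        for cs in classified:
            for beep in terminal_events(cs, config):
                events.append({
                    "kind": "beep", "time": beep.time,
                    "duration": beep.duration,
                    "tone": beep.tone.value, "cause": beep.cause.value,
                })
    events.sort(key=lambda e: (e["time"], 0 if e["kind"] == "bar" else 1))
    return events


def write_event_log(events: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps({"time_ms": e["time"], **{k: v for k, v in e.items()
                                                          if k != "time"}}) + "\n")


def read_event_log(path: str | Path) -> list[dict]:
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                events.append(json.loads(line))
    return events
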