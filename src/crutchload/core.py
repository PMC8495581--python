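"""Domain model for partial weight-bearing prescriptions on forearm crutches.

A clinician prescribes the fraction of body weight a patient's crutches
should carry at the peak of each support (stance of the crutch), together
with a symmetric tolerance band around that ideal load and — in bilateral
gait — a tolerance on the left/right load difference.  Everything downstream
(support classification, feedback events, walk statistics) consumes the
types and window arithmetic defined here.

Units are the clinical ones throughout: kilogram-force (kgf) for loads,
milliseconds for times, hertz for sampling rates.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

#: Conversion constant for callers who need SI forces; loads in this
#: package are always expressed in kilogram-force.
NEWTONS_PER_KGF = 9.80665

#: Sampling-rate presets offered by the acquisition hardware.
SAMPLING_RATE_PRESETS = (20.0, 40.0, 80.0)


class ConfigurationError(ValueError):
    """Raised when a session configuration is internally inconsistent."""


class NotApplicableError(ValueError):
    """Raised when a bilateral-only quantity is requested in unilateral gait."""


class GaitMode(str, enum.Enum):
    UNILATERAL = "unilateral"
    BILATERAL = "bilateral"


class AccuracyStatus(str, enum.Enum):
    """Outcome of comparing a support's peak load with the tolerance window."""

    CORRECT = "correct"
    OVERLOAD = "overload"
    UNDERLOAD = "underload"


class WindowScope(str, enum.Enum):
    """Whether a tolerance window applies to the summed load or to one crutch."""

    TOTAL = "total"
    PER_CRUTCH = "per_crutch"


@dataclass(frozen=True)
class SessionConfig:
    """The clinician's prescription plus acquisition parameters for one session.

    Parameters
    ----------
    body_weight : float
        Subject body weight in kgf; must be positive.
    ideal_load_fraction : float
        Fraction of body weight the crutches should bear at peak
        (0.50 means half the body weight is transferred to the crutches).
    accuracy_tolerance : float
        Half-width of the correct-load window as a fraction of the ideal
        load; 0.05 yields the 95–105 % window.
    balance_tolerance : float
        Maximum allowed left/right peak difference as a fraction of the
        ideal *total* load; meaningful only in bilateral gait.
    simultaneity_window : float
        Maximum onset lag (ms) between the two crutches for a stride to
        count as simultaneous.
    onset_threshold : float or None
        Force level (kgf) that marks the start of a support; ``None``
        selects ``max(1 kgf, 2 % of the ideal total load)``.
    min_support_duration : float
        Shortest excursion (ms) accepted as a genuine support.
    """

    subject_id: str = "anonymous"
    body_weight: float = 70.0
    ideal_load_fraction: float = 0.50
    accuracy_tolerance: float = 0.05
    balance_tolerance: float = 0.05
    gait_mode: GaitMode = GaitMode.BILATERAL
    sampling_rate: float = 80.0
    simultaneity_window: float = 100.0
    onset_threshold: float | None = None
    min_support_duration: float = 200.0

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ConfigurationError(f"body_weight must be > 0, got {self.body_weight}")
        if not 0 < self.ideal_load_fraction <= 1:
            raise ConfigurationError(
                f"ideal_load_fraction must be in (0, 1], got {self.ideal_load_fraction}"
            )
        if not 0 <= self.accuracy_tolerance < 1:
            raise ConfigurationError(
                f"accuracy_tolerance must be in [0, 1), got {self.accuracy_tolerance}"
            )
        if not 0 <= self.balance_tolerance < 1:
            raise ConfigurationError(
                f"balance_tolerance must be in [0, 1), got {self.balance_tolerance}"
            )
        if not 10.0 <= self.sampling_rate <= 80.0:
            raise ConfigurationError(
                f"sampling_rate must be in [10, 80] Hz, got {self.sampling_rate}"
            )
        if self.simultaneity_window < 0:
            raise ConfigurationError("simultaneity_window must be >= 0 ms")
        if self.min_support_duration <= 0:
            raise ConfigurationError("min_support_duration must be > 0 ms")
        if self.onset_threshold is not None and self.onset_threshold <= 0:
            raise ConfigurationError("onset_threshold must be > 0 kgf")
        # allow enum values passed as plain strings (e.g. from JSON)
        object.__setattr__(self, "gait_mode", GaitMode(self.gait_mode))

    @property
    def ideal_total(self) -> float:
        """Prescribed peak load on the crutches combined, in kgf."""
        return self.body_weight * self.ideal_load_fraction

    @property
    def effective_onset_threshold(self) -> float:
        """Support-detection onset threshold in kgf (resolved default)."""
        if self.onset_threshold is not None:
            return self.onset_threshold
        return max(1.0, 0.02 * self.ideal_total)

    @property
    def balance_applicable(self) -> bool:
        return self.gait_mode is GaitMode.BILATERAL

    # -- JSON round-trip ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["gait_mode"] = self.gait_mode.value
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionConfig":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"invalid session-config JSON: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown session-config field(s): {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class ToleranceWindow:
    """Inclusive band [lower, upper] around the ideal load, in kgf."""

    ideal: float
    lower: float
    upper: float
    scope: WindowScope

    def contains(self, load: float) -> bool:
        return self.lower <= load <= self.upper


def tolerance_window(config: SessionConfig, scope: WindowScope | str = WindowScope.TOTAL) -> ToleranceWindow:
    """Correct-load window for the summed or per-crutch peak load.

    The window is symmetric around the ideal load with half-width
    ``accuracy_tolerance × ideal``.  In bilateral gait the per-crutch
    window is exactly half the total window (the ideal load is assumed
    evenly split between the crutches).

    Examples
    --------
    >>> cfg = SessionConfig(body_weight=100.0)
    >>> tolerance_window(cfg)
    ToleranceWindow(ideal=50.0, lower=47.5, upper=52.5, scope=<WindowScope.TOTAL: 'total'>)
    """
    scope = WindowScope(scope)
    ideal = config.ideal_total
    if scope is WindowScope.PER_CRUTCH:
        if config.gait_mode is not GaitMode.BILATERAL:
            raise NotApplicableError("per-crutch window is only defined for bilateral gait")
        ideal = ideal / 2.0
    half = ideal * config.accuracy_tolerance
    return ToleranceWindow(ideal=ideal, lower=ideal - half, upper=ideal + half, scope=scope)


def balance_limit(config: SessionConfig) -> float:
    """Maximum allowed |left − right| peak difference, in kgf.

    Defined as ``balance_tolerance × ideal_total`` (e.g. 5 % of a 50 kgf
    ideal total is 2.5 kgf).  Only meaningful in bilateral gait.
    """
    if config.gait_mode is not GaitMode.BILATERAL:
        raise NotApplicableError(
            "balance limit is not applicable in unilateral gait"
        )
    return config.balance_tolerance * config.ideal_total


def percent_of_ideal(total_peak: float, config: SessionConfig) -> float:
    """Express a summed peak load as a percentage of the ideal total load.

    Returns the unrounded percentage; reports round to two decimals for
    display.  ``total_peak`` must be non-negative.
    """
    if total_peak < 0:
        raise ValueError(f"total_peak must be >= 0, got {total_peak}")
    return 100.0 * total_peak / config.ideal_total


def percent_window(config: SessionConfig) -> tuple[float, float]:
    """Correct-load window expressed in percent of ideal, inclusive bounds."""
    half = 100.0 * config.accuracy_tolerance
    return 100.0 - half, 100.0 + half
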