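"""Synthetic bilateral crutch-force walks with known ground truth.

Every support is a raised-cosine hump

    f(t) = P · ½ (1 − cos(2π (t − onset) / D)),   t ∈ [onset, onset + D]

with per-stride total peak drawn from a normal distribution expressed in
percent of the prescribed ideal load, split between the two crutches by
a per-stride left share, and the two onsets offset by a drawn
asynchrony.  Optional loading hesitation (a "fluctuation") is injected
as a multiplicative notch at mid-support, splitting the hump into two
prominent peaks; additive Gaussian noise is clamped at zero force.

The generator is the testing ground for the whole pipeline: it returns
per-stride ground truth (programmed peaks, onsets, fluctuation flags) so
detection and classification can be scored against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigurationError, SessionConfig
from .detection import detect_supports, pair_supports
from .classify import classify_stride, count_walk
from .signal_io import ForceSeries


@dataclass(frozen=True)
class WalkProfile:
    """Stochastic description of one simulated walk.

    Defaults emulate the pilot's walk structure: 10 strides at a free
    cadence of about 1.5 s with supports a little over one second long,
    sampled at 80 Hz.  ``target_pct_mean`` / ``sd`` set the walker's
    load-accuracy behaviour in percent of the ideal total load (100 ± a
    few percent is a compliant walker; the baseline walkers in the pilot
    ranged from roughly 60 % to 200 %).
    """

    n_strides: int = 10
    cadence_period: float = 1500.0      # ms between successive stride onsets
    support_duration: float = 1100.0    # ms, crutch stance length
    target_pct_mean: float = 100.0      # percent of ideal total load
    target_pct_sd: float = 3.0
    left_share_mean: float = 0.5        # fraction of the total carried left
    left_share_sd: float = 0.01
    asynchrony_ms_mean: float = 0.0     # left onset minus right onset
    asynchrony_ms_sd: float = 20.0
    fluctuation_prob: float = 0.0
    fluctuation_depth: float = 0.3      # notch depth, fraction of the hump
    noise_sd: float = 0.2               # kgf
    sampling_rate: float = 80.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_strides < 0:
            raise ConfigurationError("n_strides must be >= 0")
        if not self.support_duration < self.cadence_period:
            raise ConfigurationError("support_duration must be < cadence_period")
        if not 0 <= self.fluctuation_prob <= 1:
            raise ConfigurationError("fluctuation_prob must be in [0, 1]")
        if not 0 <= self.fluctuation_depth < 1:
            raise ConfigurationError("fluctuation_depth must be in [0, 1)")
        for name in ("target_pct_sd", "left_share_sd", "asynchrony_ms_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 < self.left_share_mean < 1:
            raise ConfigurationError("left_share_mean must be in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "WalkProfile":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"invalid walk-profile JSON: {exc}") from exc
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown walk-profile field(s): {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _hump(t: np.ndarray, onset: float, duration: float, peak: float,
          fluctuate: bool, depth: float) -> np.ndarray:
    """Raised-cosine support with an optional fluctuation notch."""
    phase = (t - onset) / duration
    inside = (phase >= 0.0) & (phase <= 1.0)
    f = np.zeros_like(t)
    f[inside] = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[inside]))
    if fluctuate and depth > 0:
        # multiplicative mid-support notch (hesitation dip), 40 % wide:
        # splits the hump into two prominent peaks with a trough whose
        # depth scales with `depth`; rescaled so the attained maximum
        # still equals the programmed peak
        centre, width = 0.5, 0.4
        u = (phase - centre) / width
        notch_zone = inside & (np.abs(u) <= 0.5)
        notch = np.zeros_like(t)
        notch[notch_zone] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[notch_zone]))
        f *= 1.0 - depth * notch
        attained = f[inside].max() if inside.any() else 0.0
        if attained > 0:
            f[inside] *= peak / attained
    return f


def simulate_walk(profile: WalkProfile, config: SessionConfig,
                  seed: int | None = None
                  ) -> tuple[ForceSeries, ForceSeries, pd.DataFrame]:
    """Generate one walk: (left series, right series, ground-truth table).

    Deterministic for a fixed seed (``seed`` argument overrides
    ``profile.seed``).  The ground-truth table has one row per programmed
    stride with the drawn total peak, per-side peaks, onsets and
    fluctuation flags.
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    ideal = config.ideal_total
    lead_in = profile.cadence_period  # quiet zone before the first stride

    rows = []
    for k in range(profile.n_strides):
        total_pct = rng.normal(profile.target_pct_mean, profile.target_pct_sd)
        total_peak = max(0.0, total_pct * ideal / 100.0)
        share = float(np.clip(rng.normal(profile.left_share_mean,
                                         profile.left_share_sd), 0.0, 1.0))
        asyn = rng.normal(profile.asynchrony_ms_mean, profile.asynchrony_ms_sd)
        base = lead_in + k * profile.cadence_period
        rows.append({
            "stride": k + 1,
            "total_peak_kgf": total_peak,
            "left_peak_kgf": total_peak * share,
            "right_peak_kgf": total_peak * (1.0 - share),
            "left_onset_ms": base + asyn,
            "right_onset_ms": base,
            "asynchrony_ms": asyn,
            "fluct_left": bool(rng.random() < profile.fluctuation_prob),
            "fluct_right": bool(rng.random() < profile.fluctuation_prob),
            "target_pct": total_pct,
        })
    truth = pd.DataFrame(rows, columns=[
        "stride", "total_peak_kgf", "left_peak_kgf", "right_peak_kgf",
        "left_onset_ms", "right_onset_ms", "asynchrony_ms",
        "fluct_left", "fluct_right", "target_pct",
    ])

    period = 1000.0 / profile.sampling_rate
    t_end = lead_in + profile.n_strides * profile.cadence_period + lead_in
    t = period * np.arange(int(np.ceil(t_end / period)) + 1)

    left_f = np.zeros_like(t)
    right_f = np.zeros_like(t)
    for r in rows:
        left_f += _hump(t, r["left_onset_ms"], profile.support_duration,
                        r["left_peak_kgf"], r["fluct_left"], profile.fluctuation_depth)
        right_f += _hump(t, r["right_onset_ms"], profile.support_duration,
                         r["right_peak_kgf"], r["fluct_right"], profile.fluctuation_depth)
    if profile.noise_sd > 0:
        left_f += rng.normal(0.0, profile.noise_sd, size=t.shape)
        right_f += rng.normal(0.0, profile.noise_sd, size=t.shape)
    left_f = np.maximum(left_f, 0.0)
    right_f = np.maximum(right_f, 0.0)

    left = ForceSeries("left", profile.sampling_rate, t, left_f, "L-sim")
    right = ForceSeries("right", profile.sampling_rate, t, right_f, "R-sim")
    return left, right, truth


def discretization_bound(profile: WalkProfile) -> float:
    """Worst-case relative peak underestimate from sampling the hump.

    The raised cosine attains its programmed peak mid-support; with
    sample spacing Δt the nearest sample can miss it by at most
    ``½ (1 − cos(π Δt / D))`` relative to the peak.
    """
    dt = 1000.0 / profile.sampling_rate
    return 0.5 * (1.0 - np.cos(np.pi * dt / profile.support_duration))


def recovery_report(profile: WalkProfile, config: SessionConfig,
                    seed: int | None = None) -> dict:
    """Simulate a walk, run detection + classification, score the recovery.

    Returns programmed vs detected stride counts, the worst relative
    peak-recovery error, and the per-stride programmed/recovered accuracy
    statuses (programmed status = classification of the programmed
    percent).
    """
    from .classify import classify_accuracy

    left, right, truth = simulate_walk(profile, config, seed=seed)
    ls = detect_supports(left, config)
    rs = detect_supports(right, config)
    strides = pair_supports(ls, rs, config)
    classified = [classify_stride(s, config) for s in strides]
    counters = count_walk(classified)

    programmed = [classify_accuracy(max(0.0, p), config) for p in truth["target_pct"]]
    recovered = [c.accuracy for c in classified]
    peak_errors = []
    for truth_peak, cs in zip(truth["total_peak_kgf"], classified):
        if truth_peak > 0:
            peak_errors.append(abs(cs.stride.total_peak - truth_peak) / truth_peak)
    return {
        "n_programmed": profile.n_strides,
        "n_detected": len(strides),
        "count_agreement": len(strides) == profile.n_strides,
        "max_peak_rel_error": max(peak_errors, default=0.0),
        "programmed_status": [s.value for s in programmed],
        "recovered_status": [s.value for s in recovered],
        "status_agreement": (len(programmed) == len(recovered)
                             and all(a is b for a, b in zip(programmed, recovered))),
        "counters": counters,
    }
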