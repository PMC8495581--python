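"""Sensor calibration, force-series containers and CSV log formats.

Two tabular log formats are defined, mirroring the acquisition database:

* the *sample log* — one row per sampling instant with left, right and
  total load plus time in ms and an ISO-8601 timestamp;
* the *support log* — one row per detected crutch support with the
  per-side maximum loads and running correct/wrong step counters.

A packaged fixture ships the pilot dataset: percent-of-ideal maximum
loads for 10 subjects × 4 walks × 10 supports, with the over/under/correct
annotation assigned to each support.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_LOG_COLUMNS = [
    "crutch_id_left",
    "crutch_id_right",
    "load_left_kgf",
    "load_right_kgf",
    "load_total_kgf",
    "time_ms",
    "timestamp_iso8601",
]

SUPPORT_LOG_COLUMNS = [
    "crutch_id_left",
    "crutch_id_right",
    "max_load_left_kgf",
    "max_load_right_kgf",
    "max_load_total_kgf",
    "support_number",
    "correct_count",
    "wrong_count",
    "time_ms",
    "timestamp_iso8601",
]

_FIXTURE_NAME = "pilot_walks.csv"
_FIXTURE_SHA256 = "ce66720728db3e59536c4f813056a96bb8f5bead98eba5868f75cba5b503e951"
_FIXTURE_N_RECORDS = 400


class ParseError(ValueError):
    """Malformed log file; the message names the offending line."""


class PackagingError(RuntimeError):
    """The packaged fixture does not match its recorded checksum."""


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class SensorCalibration:
    """Linear millivolt → kilogram-force map for one crutch sensor.

    ``offset`` is the reading at zero load and ``max_mv`` the saturation
    bound of the ADC; ``gain`` is in kgf per millivolt.
    """

    sensor_id: str
    gain: float
    offset: float
    max_mv: float

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.offset < 0:
            raise ValueError(f"offset must be >= 0, got {self.offset}")
        if self.max_mv <= self.offset:
            raise ValueError("max_mv must exceed offset")

    @classmethod
    def from_json(cls, path: str | Path) -> "SensorCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            sensor_id=d["sensor_id"],
            gain=d["gain_kgf_per_mv"],
            offset=d["offset_mv"],
            max_mv=d["max_mv"],
        )


def mv_to_kgf(raw, cal: SensorCalibration):
    """Convert raw sensor millivolts to kgf: ``(raw − offset) × gain``.

    Readings slightly below the offset (electrical noise around zero
    load) clamp to 0 kgf.  Readings above ``max_mv`` are converted at
    the saturation bound and flagged.

    Returns
    -------
    (force, saturated)
        ``force`` in kgf and a boolean saturation flag, scalars or
        arrays matching the input shape.
    """
    raw_arr = np.asarray(raw, dtype=float)
    if np.any(raw_arr < 0):
        raise ValueError("negative millivolt reading")
    saturated = raw_arr > cal.max_mv
    clipped = np.minimum(raw_arr, cal.max_mv)
    force = np.maximum((clipped - cal.offset) * cal.gain, 0.0)
    if np.isscalar(raw) or np.ndim(raw) == 0:
        return float(force), bool(saturated)
    return force, saturated


# ---------------------------------------------------------------------------
# force series

@dataclass
class ForceSeries:
    """Uniformly sampled force signal of one crutch, in kgf.

    ``time_ms`` is milliseconds since session start, strictly increasing;
    spacing must equal ``1000 / sampling_rate`` within a small jitter
    tolerance.
    """

    side: str
    sampling_rate: float
    time_ms: np.ndarray
    force_kgf: np.ndarray
    crutch_id: str = ""

    #: allowed deviation of inter-sample spacing from the nominal period,
    #: as a fraction of that period
    JITTER_TOLERANCE = 0.01

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.force_kgf = np.asarray(self.force_kgf, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.time_ms.shape != self.force_kgf.shape:
            raise ValueError("time and force arrays must have equal length")
        if len(self.time_ms) and np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.force_kgf < 0):
            raise ValueError("forces must be non-negative")

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def is_uniform(self) -> bool:
        if len(self) < 2:
            return True
        dt = np.diff(self.time_ms)
        return bool(np.all(np.abs(dt - self.period_ms) <= self.JITTER_TOLERANCE * self.period_ms))


def resample(series: ForceSeries, target_hz: float) -> ForceSeries:
    """Linearly interpolate a series onto a uniform grid at ``target_hz``.

    The new grid starts at the first sample time and ends at or before
    the last.  Resampling to the series' own rate returns an identical
    copy.
    """
    if not 10.0 <= target_hz <= 80.0:
        raise ValueError(f"target rate must be in [10, 80] Hz, got {target_hz}")
    if len(series) < 2:
        raise ValueError("cannot resample a series with fewer than 2 samples")
    if target_hz == series.sampling_rate:
        return ForceSeries(series.side, series.sampling_rate,
                           series.time_ms.copy(), series.force_kgf.copy(),
                           series.crutch_id)
    period = 1000.0 / target_hz
    t0, t1 = series.time_ms[0], series.time_ms[-1]
    n = int(np.floor((t1 - t0) / period)) + 1
    new_t = t0 + period * np.arange(n)
    new_f = np.interp(new_t, series.time_ms, series.force_kgf)
    return ForceSeries(series.side, target_hz, new_t, new_f, series.crutch_id)


# ---------------------------------------------------------------------------
# sample log

def write_sample_log(left: ForceSeries, right: ForceSeries, path: str | Path,
                     start_timestamp: str = "1970-01-01T00:00:00") -> None:
    """Write an aligned left/right series pair as a sample-log CSV.

    Both series must share the same time base.  Timestamps are the start
    timestamp advanced by each sample's offset.
    """
    if len(left) != len(right) or not np.array_equal(left.time_ms, right.time_ms):
        raise ValueError("left and right series must share an identical time base")
    t0 = pd.Timestamp(start_timestamp)
    stamps = t0 + pd.to_timedelta(left.time_ms, unit="ms")
    df = pd.DataFrame({
        "crutch_id_left": left.crutch_id or "L",
        "crutch_id_right": right.crutch_id or "R",
        "load_left_kgf": left.force_kgf,
        "load_right_kgf": right.force_kgf,
        "load_total_kgf": left.force_kgf + right.force_kgf,
        "time_ms": left.time_ms,
        "timestamp_iso8601": [s.isoformat() for s in stamps],
    })
    df.to_csv(path, index=False)


def read_sample_log(path: str | Path, sampling_rate: float | None = None
                    ) -> tuple[ForceSeries, ForceSeries]:
    """Read a sample-log CSV back into a (left, right) series pair.

    Validates the header, strict time monotonicity and the left+right =
    total conservation on every row; violations raise :class:`ParseError`
    naming the first offending line (1-based, counting the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty sample log") from None
    if list(df.columns) != SAMPLE_LOG_COLUMNS:
        raise ParseError(f"{path}: line 1: malformed header {list(df.columns)}")
    if len(df) == 0:
        raise ParseError(f"{path}: empty sample log")
    t = df["time_ms"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ParseError(f"{path}: line {bad[0] + 3}: non-monotone time_ms")
    mismatch = np.nonzero(
        ~np.isclose(df["load_left_kgf"] + df["load_right_kgf"],
                    df["load_total_kgf"], atol=1e-9)
    )[0]
    if mismatch.size:
        raise ParseError(
            f"{path}: line {mismatch[0] + 2}: load_total_kgf != left + right"
        )
    if sampling_rate is None:
        sampling_rate = 1000.0 / float(np.median(np.diff(t))) if len(t) > 1 else 80.0
    left = ForceSeries("left", sampling_rate, t, df["load_left_kgf"].to_numpy(float),
                       str(df["crutch_id_left"].iloc[0]))
    right = ForceSeries("right", sampling_rate, t, df["load_right_kgf"].to_numpy(float),
                        str(df["crutch_id_right"].iloc[0]))
    return left, right


# ---------------------------------------------------------------------------
# support log

def write_support_log(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-support maxima table with cumulative step counters."""
    missing = [c for c in SUPPORT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"support log missing column(s): {missing}")
    df[SUPPORT_LOG_COLUMNS].to_csv(path, index=False)


def read_support_log(path: str | Path) -> pd.DataFrame:
    """Read a support-log CSV, checking counter integrity.

    The running correct/wrong counters are cumulative within a walk and
    must be non-decreasing; a decrease raises :class:`ParseError`.
    """
    path = Path(path)
    try:
        # string columns pass through verbatim ("" stays "", not NaN):
        # an empty load cell means "no device on that side", not zero
        df = pd.read_csv(path, converters={
            "crutch_id_left": str, "crutch_id_right": str,
            "timestamp_iso8601": str,
        })
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty support log") from None
    if list(df.columns) != SUPPORT_LOG_COLUMNS:
        raise ParseError(f"{path}: line 1: malformed header {list(df.columns)}")
    for col in ("correct_count", "wrong_count"):
        vals = df[col].to_numpy()
        bad = np.nonzero(np.diff(vals) < 0)[0]
        if bad.size:
            raise ParseError(f"{path}: line {bad[0] + 3}: decreasing {col}")
    return df


# ---------------------------------------------------------------------------
# pilot fixture

def load_pilot_fixture() -> pd.DataFrame:
    """Load the bundled pilot walk dataset.

    Returns a DataFrame with columns ``subject`` (1–10), ``walk`` (0–3),
    ``support`` (1–10), ``percent`` (peak load as percent of the ideal
    total, two decimals) and ``annotation`` (``correct`` / ``overload`` /
    ``underload`` as assigned when the dataset was recorded).  Walk 0 is
    the no-feedback baseline; walks 1–3 used double-bar feedback.

    The file's checksum is verified on load to guard against packaging
    corruption.
    """
    data = (resources.files("crutchload") / "data" / _FIXTURE_NAME).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise PackagingError(
            f"pilot fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(data))
    if len(df) != _FIXTURE_N_RECORDS:
        raise PackagingError(f"pilot fixture has {len(df)} records, expected 400")
    return df
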