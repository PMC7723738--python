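"""Breath-trace containers and the single-value CO estimator.

A breath test on the MoMba meter records exhaled air through an
electrochemical CO sensor for 20 seconds at 5 Hz.  The reading of
interest is the end-expiratory (alveolar) plateau; the sensor also
carries a baseline offset from recent charging and ambient pollution
that has to be removed.  The estimator here condenses the 100-sample
trace to one ppm value in three steps: estimate the pre-exhalation
baseline, window the samples above half of the maximum rise, and take
the median of that window net of the baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BreathTrace",
    "COEstimate",
    "estimate_baseline",
    "momba_co_estimate",
    "read_traces",
    "write_traces",
]

#: QC flag names attached to estimates.
NO_EXHALATION = "no_exhalation_detected"
TRUNCATED = "truncated_trace"
NEGATIVE_BEFORE_CLIP = "negative_before_clip"


@dataclass
class BreathTrace:
    """One raw breath test: an ordered CO time series plus device metadata.

    Parameters
    ----------
    test_id, participant_id, device_id
        Opaque identifiers.
    timestamp
        Naive local time of the test (ISO-8601 when serialized).
    samples
        CO readings in ppm, non-negative, in acquisition order.
    sample_rate
        Samples per second; the deployed sensor ran at 5 Hz.
    duration
        Nominal acquisition length in seconds (20 s deployed).
    pre_exhalation_count
        Number of leading samples recorded before exhalation onset;
        these carry only the baseline offset.
    quantized
        True when the device snapped readings to its 1 ppm resolution.
    truncated
        True when fewer samples than ``sample_rate * duration`` were
        recorded (interrupted test).
    """

    test_id: str
    participant_id: str
    timestamp: pd.Timestamp
    samples: np.ndarray
    sample_rate: float = 5.0
    duration: float = 20.0
    pre_exhalation_count: int = 0
    device_id: str = "sensordrone"
    quantized: bool = False
    truncated: bool = field(default=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("trace must contain at least one sample")
        if np.any(self.samples < 0) or not np.all(np.isfinite(self.samples)):
            raise ValueError("CO samples must be finite and non-negative")
        expected = round(self.sample_rate * self.duration)
        if self.samples.size < expected and not self.truncated:
            raise ValueError(
                f"trace has {self.samples.size} samples, expected {expected}; "
                "set truncated=True for interrupted tests"
            )
        if not 0 <= self.pre_exhalation_count < self.samples.size:
            raise ValueError("pre_exhalation_count must lie inside the trace")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def is_complete(self) -> bool:
        return self.samples.size >= round(self.sample_rate * self.duration)


@dataclass(frozen=True)
class COEstimate:
    """The single ppm value summarizing a trace, with QC provenance.

    ``value`` is clipped at zero (a CO concentration cannot be
    negative); ``window_indices`` records which samples entered the
    median; ``qc_flags`` collects anomalies rather than raising.
    """

    value: float
    baseline: float
    window_indices: np.ndarray
    raw_max: float
    qc_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("estimate must be non-negative after clipping")


def estimate_baseline(trace: BreathTrace, fallback_seconds: float = 2.0) -> float:
    """Baseline sensor offset for one trace, in ppm.

    The median of the recorded pre-exhalation samples.  When the trace
    carries no pre-exhalation segment (``pre_exhalation_count == 0``)
    the fallback is the minimum over the first ``fallback_seconds`` of
    the trace, a conservative proxy for the offset.
    """
    k = trace.pre_exhalation_count
    if k >= 1:
        return float(np.median(trace.samples[:k]))
    n = max(1, round(trace.sample_rate * fallback_seconds))
    return float(np.min(trace.samples[:n]))


def momba_co_estimate(
    trace: BreathTrace,
    mode: str = "corrected",
    min_rise: float = 1.0,
) -> COEstimate:
    """Condense a breath trace to one CO value in ppm.

    Three steps: (1) estimate the baseline offset ``b``; (2) locate the
    maximum and capture the samples at or above 50% of it; (3) take the
    median of the captured window and remove the baseline offset.

    Two orderings of steps (2)-(3) are exposed:

    ``corrected`` (default)
        Threshold on the baseline-corrected signal ``c = samples - b``:
        the window is ``{i : c_i >= 0.5 * max(c)}`` and the value is the
        median of ``c`` over the window.  Robust to large charging or
        pollution offsets, which would otherwise drag the half-maximum
        threshold below the whole trace.
    ``literal``
        Threshold on the raw samples and subtract ``b`` from the window
        median afterwards.

    Either way the result is clipped at 0 ppm.  A maximum rise below
    ``min_rise`` ppm (default one resolution step) flags
    ``no_exhalation_detected`` instead of raising.
    """
    if mode not in ("corrected", "literal"):
        raise ValueError(f"mode must be 'corrected' or 'literal', got {mode!r}")
    b = estimate_baseline(trace)
    flags: set[str] = set()
    if trace.truncated or not trace.is_complete:
        flags.add(TRUNCATED)

    x = trace.samples
    if mode == "corrected":
        c = x - b
        m = float(np.max(c))
        window = np.flatnonzero(c >= 0.5 * m)
        raw_value = float(np.median(c[window]))
    else:
        m_raw = float(np.max(x))
        window = np.flatnonzero(x >= 0.5 * m_raw)
        raw_value = float(np.median(x[window])) - b
        m = m_raw - b

    if m < min_rise:
        flags.add(NO_EXHALATION)
    if raw_value < 0:
        flags.add(NEGATIVE_BEFORE_CLIP)
    return COEstimate(
        value=max(0.0, raw_value),
        baseline=b,
        window_indices=window,
        raw_max=float(np.max(x)),
        qc_flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# File interchange: long-format CSV of samples plus a JSON metadata sidecar.

_TRACE_COLUMNS = ["test_id", "participant_id", "timestamp", "sample_index", "co_ppm"]


def write_traces(traces: list[BreathTrace], csv_path: str | Path) -> None:
    """Write traces as long-format CSV plus a ``.meta.json`` sidecar."""
    csv_path = Path(csv_path)
    frames = []
    meta = {}
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "test_id": t.test_id,
                    "participant_id": t.participant_id,
                    "timestamp": t.timestamp.isoformat(),
                    "sample_index": np.arange(t.n_samples),
                    "co_ppm": t.samples,
                }
            )
        )
        meta[t.test_id] = {
            "sample_rate_hz": t.sample_rate,
            "duration_s": t.duration,
            "pre_exhalation_count": t.pre_exhalation_count,
            "device_id": t.device_id,
            "quantized": t.quantized,
            "truncated": t.truncated,
        }
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_TRACE_COLUMNS)
    )
    df.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1))


def read_traces(csv_path: str | Path) -> list[BreathTrace]:
    """Read traces written by :func:`write_traces`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file missing columns: {sorted(missing)}")
    sidecar = csv_path.with_suffix(".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    traces = []
    for test_id, grp in df.groupby("test_id", sort=False):
        grp = grp.sort_values("sample_index")
        m = meta.get(str(test_id), {})
        traces.append(
            BreathTrace(
                test_id=str(test_id),
                participant_id=str(grp["participant_id"].iloc[0]),
                timestamp=pd.Timestamp(grp["timestamp"].iloc[0]),
                samples=grp["co_ppm"].to_numpy(dtype=float),
                sample_rate=m.get("sample_rate_hz", 5.0),
                duration=m.get("duration_s", 20.0),
                pre_exhalation_count=m.get("pre_exhalation_count", 0),
                device_id=m.get("device_id", "sensordrone"),
                quantized=m.get("quantized", False),
                truncated=m.get("truncated", False),
            )
        )
    return traces
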