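"""EMG and lever-force conditioning, and cross-correlation validation.

The EMG chain reproduces the standard linear-envelope pipeline: high-pass at
30 Hz (removes movement artifact and DC), full-wave rectification,
anti-aliased downsampling to 100 Hz, then low-pass at 2.5 Hz.  Lever-force
channels are low-passed at 10 Hz and downsampled to 100 Hz.  All filters are
zero-phase 4th-order Butterworth (forward-backward), the package's
documented dialect; only the cutoffs are prescribed by the protocol.

Predicted muscle forces are compared with EMG envelopes by the zero-lag
cross-correlation r (Pearson, mean removed), skipping muscles whose EMG is
effectively zero or whose predicted force never reaches 0.3 N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

ENVELOPE_RATE_HZ = 100.0
FORCE_SKIP_THRESHOLD_N = 0.3
#: envelope peak below this fraction of the record-set reference amplitude
#: counts as "effectively zero" (the criterion itself is a package decision)
EMG_ZERO_FRACTION = 0.05


@dataclass
class EMGRecord:
    """One EMG channel: raw samples (mV) and the processed 100 Hz envelope."""

    channel: str
    raw_mV: np.ndarray
    source_rate_hz: float
    envelope_mV: Optional[np.ndarray] = None
    envelope_rate_hz: float = ENVELOPE_RATE_HZ

    def __post_init__(self):
        self.raw_mV = np.asarray(self.raw_mV, dtype=float).ravel()
        if not self.source_rate_hz > 0:
            raise ValueError("source rate must be positive")
        if self.envelope_mV is not None:
            self.envelope_mV = np.asarray(self.envelope_mV, dtype=float).ravel()

    def process(self) -> "EMGRecord":
        self.envelope_mV = emg_envelope(self.raw_mV, self.source_rate_hz)
        return self


def _sosfiltfilt(x, cutoff, rate, btype):
    sos = signal.butter(4, cutoff, btype=btype, fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def _resample_to(x: np.ndarray, source_rate: float, target_rate: float) -> np.ndarray:
    """Anti-aliased polyphase resampling to the target rate."""
    frac = Fraction(target_rate / source_rate).limit_denominator(10000)
    return signal.resample_poly(
        x, frac.numerator, frac.denominator, axis=0, padtype="line"
    )


def emg_envelope(raw_mV: np.ndarray, source_rate_hz: float) -> np.ndarray:
    """Linear envelope at 100 Hz: 30 Hz high-pass, rectify, downsample to
    100 Hz, 2.5 Hz low-pass (stages in that order)."""
    if source_rate_hz <= 60.0:
        raise ValueError(
            f"source rate {source_rate_hz} Hz too low for a 30 Hz high-pass"
        )
    x = np.asarray(raw_mV, dtype=float).ravel()
    x = _sosfiltfilt(x, 30.0, source_rate_hz, "high")
    x = np.abs(x)
    x = _resample_to(x, source_rate_hz, ENVELOPE_RATE_HZ)
    x = _sosfiltfilt(x, 2.5, ENVELOPE_RATE_HZ, "low")
    return x


def process_lever_force(raw_N: np.ndarray, source_rate_hz: float) -> np.ndarray:
    """Lever-force conditioning: 10 Hz low-pass then resample to 100 Hz."""
    if source_rate_hz < 200.0:
        raise ValueError(f"source rate {source_rate_hz} Hz too low (need >= 200)")
    x = np.asarray(raw_N, dtype=float).ravel()
    x = _sosfiltfilt(x, 10.0, source_rate_hz, "low")
    return _resample_to(x, source_rate_hz, ENVELOPE_RATE_HZ)


def cross_correlation_zero_lag(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag cross-correlation r in [-1, 1] (mean-removed, normalized)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("series must have equal length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cross-correlation undefined for a constant series")
    r = float(xc @ yc / (nx * ny))
    return max(-1.0, min(1.0, r))


def scale_emg_for_comparison(envelope_mV: np.ndarray, fmax_N: float) -> np.ndarray:
    """Plotting-only normalization of an EMG envelope to force units.

    The envelope is scaled so its peak equals the muscle's maximum force; if
    the maximum force is below 0.3 N the fixed gauge 100 mV = 1 N is used.
    The zero-lag correlation is scale-invariant, so this never enters r.
    """
    if fmax_N < 0:
        raise ValueError("maximum force must be non-negative")
    env = np.asarray(envelope_mV, dtype=float)
    if fmax_N < FORCE_SKIP_THRESHOLD_N:
        return env / 100.0
    peak = np.max(np.abs(env))
    if peak == 0.0:
        return np.zeros_like(env)
    return env * (fmax_N / peak)


@dataclass
class ValidationReport:
    """Per-muscle zero-lag correlation against the EMG envelope, or the
    reason the comparison was skipped."""

    entries: dict = field(default_factory=dict)

    def add_r(self, muscle: str, r: float):
        self.entries[muscle] = {"r": r}

    def add_skip(self, muscle: str, reason: str):
        self.entries[muscle] = {"skip_reason": reason}

    def r(self, muscle: str):
        return self.entries.get(muscle, {}).get("r")

    def skip_reason(self, muscle: str):
        return self.entries.get(muscle, {}).get("skip_reason")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, e in self.entries.items():
            rows.append((m, e.get("r"), e.get("skip_reason")))
        return pd.DataFrame(rows, columns=["muscle", "r", "skip_reason"])


def build_validation_report(
    predicted_forces: dict,
    emg_envelopes: dict,
    force_threshold_N: float = FORCE_SKIP_THRESHOLD_N,
    emg_zero_fraction: float = EMG_ZERO_FRACTION,
) -> ValidationReport:
    """Compare predicted muscle-force series with EMG envelopes.

    ``predicted_forces`` and ``emg_envelopes`` map channel/muscle name to
    aligned 100 Hz series.  Skip rules: the EMG amplitude is effectively zero
    (envelope peak below ``emg_zero_fraction`` of the record set's robust
    reference amplitude, the 95th percentile of all pooled envelope samples),
    or the predicted force never reaches ``force_threshold_N``.
    """
    report = ValidationReport()
    pooled = np.concatenate(
        [np.abs(np.asarray(v, float).ravel()) for v in emg_envelopes.values()]
    ) if emg_envelopes else np.zeros(1)
    reference = float(np.percentile(pooled, 95)) if pooled.size else 0.0
    for muscle, env in emg_envelopes.items():
        if muscle not in predicted_forces:
            continue
        force = np.asarray(predicted_forces[muscle], dtype=float).ravel()
        env = np.asarray(env, dtype=float).ravel()
        if force.shape != env.shape:
            raise ValueError(
                f"{muscle}: force ({force.shape}) and envelope ({env.shape}) "
                "series are misaligned"
            )
        peak_env = float(np.max(np.abs(env))) if env.size else 0.0
        if peak_env <= emg_zero_fraction * reference or peak_env == 0.0:
            report.add_skip(muscle, "emg_effectively_zero")
            continue
        if float(np.max(force)) < force_threshold_N:
            report.add_skip(muscle, "force_below_0.3N")
            continue
        report.add_r(muscle, cross_correlation_zero_lag(force, env))
    return report
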