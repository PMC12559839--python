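"""Continuous-recording preprocessing and onset-locked epoching.

Fixed stage order: resample (500 Hz) -> line-noise notch -> segment
averaging (SenSight leads) -> common-average rereference per hemisphere ->
1-50 Hz bandpass -> epoch on the -2000..+1000 ms grid. All filtering is
zero-phase (forward-backward), so perievent latencies are unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (
    EPOCH_END_MS,
    EPOCH_START_MS,
    FOUR_CONTACT_LABELS,
    PROC_RATE_HZ,
    EpochSet,
    RecordingSession,
    epoch_time_grid,
)

logger = logging.getLogger(__name__)


def resample(session: RecordingSession, target_rate: float = PROC_RATE_HZ) -> RecordingSession:
    """Anti-aliased polyphase downsampling to target_rate."""
    src = session.sampling_rate_hz
    if target_rate == src:
        return session.copy_with()
    if target_rate > src:
        raise ValueError("upsampling is not supported; target rate must be <= source rate")
    frac = Fraction(target_rate / src).limit_denominator(1000)
    data = signal.resample_poly(session.data, frac.numerator, frac.denominator, axis=1)
    return session.copy_with(data=data, sampling_rate_hz=target_rate)


def remove_line_noise(session: RecordingSession, line_hz: float = 60.0,
                      harmonics: int = 2, q: float = 35.0) -> RecordingSession:
    """Zero-phase IIR notch at the line frequency and its harmonics.

    harmonics counts notched multiples of line_hz including the fundamental;
    multiples at or above Nyquist are skipped.
    """
    nyq = session.sampling_rate_hz / 2.0
    if line_hz >= nyq:
        raise ValueError("line frequency must be below Nyquist")
    data = session.data
    for k in range(1, harmonics + 1):
        f = k * line_hz
        if f >= nyq:
            break
        b, a = signal.iirnotch(f, q, fs=session.sampling_rate_hz)
        data = signal.filtfilt(b, a, data, axis=1)
    return session.copy_with(data=data)


def average_segments(session: RecordingSession) -> RecordingSession:
    """Average the three radial segments of each segmented contact row.

    2A,2B,2C -> "2" and 3A,3B,3C -> "3" (samplewise arithmetic mean);
    contacts 1 and 4 pass through. A 4-channel session is returned unchanged.
    """
    if len(session.channels) == 4:
        logger.info("average_segments: session already has 4 contacts; pass-through")
        return session.copy_with()
    idx = {lab: i for i, lab in enumerate(session.channels)}
    required = {"1", "2A", "2B", "2C", "3A", "3B", "3C", "4"}
    missing = required - set(idx)
    if missing:
        raise ValueError(f"segmented lead is missing labels: {sorted(missing)}")
    d = session.data
    out = np.stack([
        d[idx["1"]],
        (d[idx["2A"]] + d[idx["2B"]] + d[idx["2C"]]) / 3.0,
        (d[idx["3A"]] + d[idx["3B"]] + d[idx["3C"]]) / 3.0,
        d[idx["4"]],
    ])
    return session.copy_with(data=out, channels=list(FOUR_CONTACT_LABELS),
                             lead_model="four_contact")


def common_average_reference(session: RecordingSession) -> RecordingSession:
    """Subtract the samplewise mean of the four contacts from each contact."""
    if len(session.channels) != 4:
        raise ValueError("common-average reference expects exactly 4 contacts "
                         "(run average_segments first)")
    data = session.data - session.data.mean(axis=0, keepdims=True)
    return session.copy_with(data=data)


def bandpass(session: RecordingSession, low: float = 1.0, high: float = 50.0) -> RecordingSession:
    """Zero-phase 4th-order Butterworth bandpass (applied forward-backward)."""
    nyq = session.sampling_rate_hz / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return session.copy_with(data=signal.sosfiltfilt(sos, session.data, axis=1))


@dataclass
class RejectionReport:
    """Trials dropped at epoching because the epoch window left the recording."""

    n_total: int = 0
    n_kept: int = 0
    dropped: list = field(default_factory=list)  # (trial_id, onset_s, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def to_dict(self) -> dict:
        return {"n_total": self.n_total, "n_kept": self.n_kept,
                "dropped": [{"trial_id": int(t), "onset_s": float(o), "reason": r}
                            for t, o, r in self.dropped]}


def epoch(session: RecordingSession, annotations: pd.DataFrame,
          window_ms=(EPOCH_START_MS, EPOCH_END_MS)):
    """Extract onset-locked trials; returns (EpochSet, RejectionReport).

    t = 0 is the sample nearest each onset. Trials whose window would leave
    the recording are dropped, logged and counted; overlapping epochs are
    extracted independently.
    """
    rate = session.sampling_rate_hz
    n_before = int(round(-window_ms[0] / 1000.0 * rate))
    n_after = int(round(window_ms[1] / 1000.0 * rate))
    n_times = n_before + n_after + 1
    report = RejectionReport(n_total=len(annotations))
    trials, tasks = [], []
    for row in annotations.itertuples(index=False):
        onset_idx = int(round(row.onset_s * rate))
        lo, hi = onset_idx - n_before, onset_idx + n_after + 1
        if lo < 0 or hi > session.n_samples:
            logger.warning("dropping trial %s (onset %.3f s): epoch window out of bounds",
                           row.trial_id, row.onset_s)
            report.dropped.append((row.trial_id, row.onset_s, "epoch window out of bounds"))
            continue
        trials.append(session.data[:, lo:hi])
        tasks.append(row.task)
    report.n_kept = len(trials)
    data = (np.stack(trials) if trials
            else np.empty((0, len(session.channels), n_times)))
    times = window_ms[0] + 1000.0 / rate * np.arange(n_times)
    epochs = EpochSet(data, times, np.array(tasks, dtype=object),
                      list(session.channels), session.participant_id,
                      session.hemisphere, rate)
    return epochs, report


def preprocess_session(session: RecordingSession, annotations: pd.DataFrame,
                       target_rate: float = PROC_RATE_HZ, line_hz: float | None = 60.0,
                       harmonics: int = 2, band=(1.0, 50.0)):
    """Run the full fixed-order chain; returns (EpochSet, RejectionReport)."""
    s = resample(session, target_rate)
    if line_hz is not None:
        s = remove_line_noise(s, line_hz, harmonics)
    if len(s.channels) == 8:
        s = average_segments(s)
    s = common_average_reference(s)
    s = bandpass(s, *band)
    return epoch(s, annotations)
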