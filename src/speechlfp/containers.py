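"""Core in-memory containers shared across the pipeline.

A recording session holds continuous multi-channel voltage from one
participant-hemisphere (one DBS lead). Epoching locks trials to speech
onset on a fixed -2000..+1000 ms grid at 500 Hz (1501 samples). Power
tensors and time-frequency maps sit on that grid with a log-spaced
frequency axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

#: processed-data sampling rate after downsampling, Hz
PROC_RATE_HZ = 500.0
#: epoch window relative to speech onset, ms (inclusive endpoints)
EPOCH_START_MS = -2000.0
EPOCH_END_MS = 1000.0
#: statistics are evaluated only on this window, ms
EVAL_WINDOW_MS = (-500.0, 1000.0)
#: baseline period used for the surrogate shuffle, ms: (-1000, -500]
SHUFFLE_BASELINE_MS = (-1000.0, -500.0)

#: analysis bands, Hz (inclusive bounds)
BANDS_HZ = {"theta": (1.0, 8.0), "beta": (13.0, 30.0)}
#: analysis windows, ms; prespeech is [-500, 0), during-speech is [0, 1000]
WINDOWS_MS = {"prespeech": (-500.0, 0.0), "during": (0.0, 1000.0)}

TASKS = ("vowel", "ddk", "sentence")

FOUR_CONTACT_LABELS = ("1", "2", "3", "4")
SEGMENTED_LABELS = ("1", "2A", "2B", "2C", "3A", "3B", "3C", "4")


def epoch_time_grid(rate_hz: float = PROC_RATE_HZ) -> np.ndarray:
    """Fixed epoch time axis in ms: -2000..+1000 inclusive (1501 samples at 500 Hz)."""
    step_ms = 1000.0 / rate_hz
    n = int(round((EPOCH_END_MS - EPOCH_START_MS) / step_ms)) + 1
    return EPOCH_START_MS + step_ms * np.arange(n)


@dataclass
class RecordingSession:
    """Continuous multi-channel LFP for one participant-hemisphere.

    data is (n_channels, n_samples) in microvolts; channels are contact
    labels along the lead shaft ("1".."4", or segmented "2A".."3C").
    """

    participant_id: str
    hemisphere: str
    sampling_rate_hz: float
    lead_model: str
    channels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere!r}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples) matching channel labels")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if len(self.channels) not in (4, 8):
            raise ValueError("a lead carries 4 or 8 contacts")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy_with(self, *, data=None, channels=None, sampling_rate_hz=None,
                  lead_model=None) -> "RecordingSession":
        return RecordingSession(
            participant_id=self.participant_id,
            hemisphere=self.hemisphere,
            sampling_rate_hz=self.sampling_rate_hz if sampling_rate_hz is None else sampling_rate_hz,
            lead_model=self.lead_model if lead_model is None else lead_model,
            channels=list(self.channels) if channels is None else list(channels),
            data=self.data if data is None else data,
        )


@dataclass
class EpochSet:
    """Onset-locked trials on the fixed -2000..+1000 ms grid.

    data is (n_trials, n_channels, n_times); tasks labels one of
    vowel/ddk/sentence per trial.
    """

    data: np.ndarray
    times_ms: np.ndarray
    tasks: np.ndarray
    channels: list[str]
    participant_id: str
    hemisphere: str
    sampling_rate_hz: float = PROC_RATE_HZ

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.tasks = np.asarray(self.tasks, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis mismatch")
        if self.data.shape[0] != self.tasks.size:
            raise ValueError("every trial needs a task label")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select_task(self, task: str) -> "EpochSet":
        keep = self.tasks == task
        return EpochSet(self.data[keep], self.times_ms, self.tasks[keep],
                        list(self.channels), self.participant_id, self.hemisphere,
                        self.sampling_rate_hz)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("times_ms", data=self.times_ms)
            f.create_dataset("tasks", data=np.array([t.encode() for t in self.tasks]))
            f.attrs["channels"] = [c for c in self.channels]
            f.attrs["participant_id"] = self.participant_id
            f.attrs["hemisphere"] = self.hemisphere
            f.attrs["sampling_rate_hz"] = self.sampling_rate_hz

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                times_ms=f["times_ms"][()],
                tasks=np.array([t.decode() for t in f["tasks"][()]], dtype=object),
                channels=list(f.attrs["channels"]),
                participant_id=str(f.attrs["participant_id"]),
                hemisphere=str(f.attrs["hemisphere"]),
                sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            )


@dataclass
class TrialPowerTensor:
    """Per-trial wavelet power, (n_trials, n_channels, n_freqs, n_times).

    kind is "linear" (power_t, >= 0) or "db" (10*log10(power_t/power_baseline)).
    edge_mask flags (freq, time) pixels within one kernel half-length of the
    epoch edge, where convolution wraps into zero padding.
    """

    power: np.ndarray
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    tasks: np.ndarray
    channels: list[str]
    participant_id: str
    hemisphere: str
    kind: str = "linear"
    edge_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "db"):
            raise ValueError("kind must be 'linear' or 'db'")
        if self.power.ndim != 4:
            raise ValueError("power must be (n_trials, n_channels, n_freqs, n_times)")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def select_task(self, task: str) -> "TrialPowerTensor":
        keep = self.tasks == task
        return TrialPowerTensor(self.power[keep], self.freqs_hz, self.times_ms,
                                self.tasks[keep], list(self.channels),
                                self.participant_id, self.hemisphere,
                                self.kind, self.edge_mask)


@dataclass
class TFMap:
    """Trial- or participant-averaged dB power, (n_channels, n_freqs, n_times)."""

    data: np.ndarray
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    channels: list[str]
    level: str = "participant"  # "participant" | "grand"
    condition: str = ""
    participant_id: str = ""
    hemisphere: str = ""
    edge_mask: np.ndarray | None = None  # (n_freqs, n_times) epoch-edge flags

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (n_channels, n_freqs, n_times)")


def annotations_frame(trial_ids, tasks, onsets_s, offsets_s) -> pd.DataFrame:
    """Tidy per-trial annotation table (trial_id, task, onset_s, offset_s)."""
    df = pd.DataFrame({
        "trial_id": np.asarray(trial_ids, dtype=int),
        "task": np.asarray(tasks, dtype=object),
        "onset_s": np.asarray(onsets_s, dtype=float),
        "offset_s": np.asarray(offsets_s, dtype=float),
    })
    bad = df["offset_s"] <= df["onset_s"]
    if bad.any():
        raise ValueError(f"offsets must exceed onsets (rows {list(df.index[bad])})")
    return df.sort_values("onset_s", ignore_index=True)
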