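"""Synthetic LFP cohort generator.

Emulates the statistical structure the downstream analysis assumes: a 1/f
(pink) background per contact, with event-locked band-limited power
modulations graded by speech-task complexity — a post-onset delta/theta
(1-8 Hz) power increase that grows from sustained vowel to DDK to sentence
repetition, and a prespeech beta (13-30 Hz) desynchronization strongest for
sentence repetition. Each generated session carries per-trial annotations
(task, onset, offset) and a ground-truth record of the injected effects, so
every pipeline stage has a recovery oracle.

Injected effects are realized by a windowed gain on the band-limited
component of the background: x -> x + (g - 1) * env(t) * bandpass(x), with
g = 10^(dB/20) and env a raised-cosine on/off envelope (50 ms ramps). The
gain multiplies the in-band content of every channel by the same factor, so
the dB effect is exact for both signs and passes unchanged through linear
channel operations (segment averaging, common-average rereferencing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (
    BANDS_HZ,
    FOUR_CONTACT_LABELS,
    SEGMENTED_LABELS,
    TASKS,
    WINDOWS_MS,
    RecordingSession,
    annotations_frame,
)

#: raised-cosine ramp length for injected modulations, ms
RAMP_MS = 50.0

# effect-size defaults (dB): ordering mirrors task complexity; magnitudes are
# free parameters of the simulation, not measured quantities
DEFAULT_THETA_EFFECT_DB = {"vowel": 1.0, "ddk": 2.5, "sentence": 3.0}
DEFAULT_BETA_EFFECT_DB = {"vowel": -0.5, "ddk": -1.0, "sentence": -2.0}
# trial-duration means follow the reported per-task medians (s)
DEFAULT_TRIAL_DURATION_S = {
    "vowel": {"mean": 0.96, "sd": 0.15},
    "ddk": {"mean": 1.27, "sd": 0.15},
    "sentence": {"mean": 1.60, "sd": 0.15},
}
DEFAULT_ITI_S = {"mean": 1.5, "sd": 0.6, "min": 0.8, "max": 3.1}


@dataclass
class SynthConfig:
    """Cohort-generation parameters.

    theta effects apply to 1-8 Hz in the during-speech window (0..+1000 ms);
    beta effects to 13-30 Hz in the prespeech window (-500..0 ms). Negative
    dB is a desynchronization. participant_sd_db is the SD of a
    participant-level offset added to every injected effect, giving the
    mixed model's random intercept something to estimate.
    """

    n_participants: int = 13
    trials_per_task: int = 40
    sampling_rate_hz: float = 2000.0
    lead_model: str = "four_contact"
    pink_exponent: float = 1.0
    theta_effect_db: dict = field(default_factory=lambda: dict(DEFAULT_THETA_EFFECT_DB))
    beta_effect_db: dict = field(default_factory=lambda: dict(DEFAULT_BETA_EFFECT_DB))
    trial_duration_s: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRIAL_DURATION_S.items()})
    iti_s: dict = field(default_factory=lambda: dict(DEFAULT_ITI_S))
    participant_sd_db: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_task < 1:
            raise ValueError("trials_per_task must be >= 1")
        if self.sampling_rate_hz < 100.0:
            raise ValueError("sampling_rate_hz must be >= 100 Hz (2 x 50 Hz analysis band)")
        if self.lead_model not in ("four_contact", "eight_contact_segmented"):
            raise ValueError(f"unknown lead_model {self.lead_model!r}")
        if not (0.0 <= self.pink_exponent <= 2.0):
            raise ValueError("pink_exponent must be in [0, 2]")
        if self.iti_s["min"] <= 0:
            raise ValueError("iti_s.min must be positive")
        if self.iti_s["sd"] < 0 or any(v["sd"] < 0 for v in self.trial_duration_s.values()):
            raise ValueError("standard deviations must be >= 0")
        for d in (self.theta_effect_db, self.beta_effect_db, self.trial_duration_s):
            missing = set(TASKS) - set(d)
            if missing:
                raise ValueError(f"effect/duration map missing tasks: {sorted(missing)}")


@dataclass
class GroundTruth:
    """What was actually injected: per-trial onsets and per task x band x window dB."""

    trials: pd.DataFrame  # trial_id, task, onset_s, offset_s
    effects: pd.DataFrame  # task, band, window, injected_db (incl. participant offset)
    participant_offset_db: float = 0.0


def pink_noise(n_samples: int, exponent: float = 1.0, sampling_rate: float = 2000.0,
               seed=None) -> np.ndarray:
    """Zero-mean 1/f^exponent noise by spectral synthesis.

    The one-sided PSD is proportional to f^-exponent, so a log-log
    periodogram fit over 1-50 Hz estimates a slope of -exponent. exponent=0
    gives white noise. Output is scaled to unit variance.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not (0.0 <= exponent <= 2.0):
        raise ValueError("exponent must be in [0, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    # complex gaussian spectrum -> gaussian time series with the target PSD
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _raised_cosine_envelope(n_samples: int, rate_hz: float, window_ms, onsets_s,
                            ramp_ms: float = RAMP_MS) -> np.ndarray:
    """Sum of per-onset on/off envelopes (clipped to 1) over the recording.

    The envelope is 1 across the whole window; the raised-cosine ramps sit
    just outside it, so the target gain holds throughout the window itself.
    """
    w0, w1 = float(window_ms[0]) / 1000.0, float(window_ms[1]) / 1000.0
    ramp = ramp_ms / 1000.0
    n_ramp = max(int(round(ramp * rate_hz)), 1)
    n_flat = int(round((w1 - w0) * rate_hz)) + 1
    up = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    shape = np.concatenate([up, np.ones(n_flat), up[::-1]])
    env = np.zeros(n_samples)
    for onset in onsets_s:
        i0 = int(round((onset + w0) * rate_hz)) - n_ramp
        if i0 < 0 or i0 + shape.size > n_samples:
            raise ValueError(
                f"modulation window for onset {onset:.3f}s exceeds recording bounds")
        env[i0:i0 + shape.size] += shape
    return np.clip(env, 0.0, 1.0)


def _band_sos(band_hz, rate_hz: float):
    nyq = rate_hz / 2.0
    lo, hi = band_hz
    return signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def inject_modulation(series: np.ndarray, band_hz, window_ms, delta_db: float,
                      onsets_s, sampling_rate: float) -> np.ndarray:
    """Change band power by delta_db inside a per-onset window.

    Applies x + (g-1)*env*bandpass(x) with g = 10^(delta_db/20); exact in dB
    for positive and negative effects, identity for delta_db = 0. Power
    outside the band and window is untouched up to filter leakage.
    """
    lo, hi = band_hz
    if not (1.0 <= lo < hi <= 50.0):
        raise ValueError("band must lie within 1-50 Hz")
    if delta_db == 0.0 or len(onsets_s) == 0:
        return np.asarray(series, dtype=float).copy()
    x = np.asarray(series, dtype=float)
    env = _raised_cosine_envelope(x.size, sampling_rate, window_ms, onsets_s)
    bp = signal.sosfiltfilt(_band_sos(band_hz, sampling_rate), x)
    g = 10.0 ** (delta_db / 20.0)
    return x + (g - 1.0) * env * bp


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws by resampling; falls back to clipping."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _trial_schedule(config: SynthConfig, rng) -> pd.DataFrame:
    n = config.trials_per_task
    tasks = np.array([t for t in TASKS for _ in range(n)], dtype=object)
    rng.shuffle(tasks)  # interleaved task order
    durs = np.array([
        max(0.3, rng.normal(config.trial_duration_s[t]["mean"],
                            config.trial_duration_s[t]["sd"]))
        for t in tasks])
    iti = config.iti_s
    itis = _truncnorm(rng, iti["mean"], iti["sd"], iti["min"], iti["max"], durs.size)
    onsets = np.empty(durs.size)
    t = 3.0  # lead-in so the first epoch (-2 s) and shuffle baseline fit
    for i in range(durs.size):
        onsets[i] = t
        t += durs[i] + itis[i]
    return annotations_frame(np.arange(durs.size), tasks, onsets, onsets + durs)


def generate_session(config: SynthConfig, participant_id: str, hemisphere: str,
                     seed=None, effect_offset_db: float = 0.0):
    """One continuous recording for a participant-hemisphere.

    Returns (RecordingSession, annotations DataFrame, GroundTruth). Channels
    carry independent pink noise; the task-specific band/window gains are
    common to all channels, so the dB effects survive segment averaging and
    common-average rereferencing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ann = _trial_schedule(config, rng)
    rate = config.sampling_rate_hz
    n_samples = int(round((ann["offset_s"].iloc[-1] + 3.0) * rate))

    labels = list(SEGMENTED_LABELS if config.lead_model == "eight_contact_segmented"
                  else FOUR_CONTACT_LABELS)
    theta = {t: config.theta_effect_db[t] + effect_offset_db if config.theta_effect_db[t] != 0 else 0.0
             for t in TASKS}
    beta = {t: config.beta_effect_db[t] + effect_offset_db if config.beta_effect_db[t] != 0 else 0.0
            for t in TASKS}

    plan = [("theta", BANDS_HZ["theta"], WINDOWS_MS["during"], theta),
            ("beta", BANDS_HZ["beta"], WINDOWS_MS["prespeech"], beta)]

    data = np.empty((len(labels), n_samples))
    for ci in range(len(labels)):
        x = pink_noise(n_samples, config.pink_exponent, rate, rng)
        for _name, band, window, eff in plan:
            if all(eff[t] == 0.0 for t in TASKS):
                continue
            bp = signal.sosfiltfilt(_band_sos(band, rate), x)
            gain = np.zeros(n_samples)
            for t in TASKS:
                if eff[t] == 0.0:
                    continue
                onsets = ann.loc[ann["task"] == t, "onset_s"].to_numpy()
                env = _raised_cosine_envelope(n_samples, rate, window, onsets)
                gain += (10.0 ** (eff[t] / 20.0) - 1.0) * env
            x = x + gain * bp
        data[ci] = x

    session = RecordingSession(participant_id, hemisphere, rate, config.lead_model,
                               labels, data)
    effects = pd.DataFrame(
        [{"task": t, "band": "theta", "window": "during", "injected_db": theta[t]}
         for t in TASKS] +
        [{"task": t, "band": "beta", "window": "prespeech", "injected_db": beta[t]}
         for t in TASKS])
    truth = GroundTruth(ann.copy(), effects, effect_offset_db)
    return session, ann, truth


def generate_cohort(config: SynthConfig):
    """All sessions for n_participants x {left, right}.

    Per-session seeds and participant-level effect offsets derive
    deterministically from config.seed, so an identical config reproduces
    the cohort exactly.
    """
    ss = np.random.SeedSequence(config.seed)
    offset_rng = np.random.default_rng(ss.spawn(1)[0])
    offsets = offset_rng.normal(0.0, config.participant_sd_db, config.n_participants)
    children = ss.spawn(1 + 2 * config.n_participants)[1:]
    out = []
    k = 0
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        for hemi in ("left", "right"):
            rng = np.random.default_rng(children[k]); k += 1
            out.append(generate_session(config, pid, hemi, rng,
                                        effect_offset_db=float(offsets[p])))
    return out


def simulate_bandpower_table(n_participants: int = 13,
                             task_means_db: dict | None = None,
                             participant_sd_db: float = 0.5,
                             noise_sd_db: float = 0.5,
                             seed: int = 0,
                             band: str = "theta",
                             window: str = "during") -> pd.DataFrame:
    """Band-power table simulated directly at the summary level.

    One row per participant x hemisphere x contact x task with
    mean_power = task mean + participant offset + N(0, noise_sd). Used for
    mixed-model calibration and degrees-of-freedom checks where the full
    signal-level pipeline adds nothing.
    """
    if task_means_db is None:
        task_means_db = {t: 0.0 for t in TASKS}
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, participant_sd_db, n_participants)
    rows = []
    for p in range(n_participants):
        for hemi in ("left", "right"):
            for contact in FOUR_CONTACT_LABELS:
                for task in TASKS:
                    rows.append({
                        "participant_id": f"P{p + 1:02d}",
                        "hemisphere": hemi,
                        "contact": contact,
                        "task": task,
                        "band": band,
                        "window": window,
                        "mean_power": task_means_db[task] + offsets[p]
                        + rng.normal(0.0, noise_sd_db),
                    })
    return pd.DataFrame(rows)
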