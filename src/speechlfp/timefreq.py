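"""Complex Morlet wavelet time-frequency decomposition and dB normalization.

Wavelet frequencies are logarithmically spaced over 1-50 Hz and the cycle
count of each wavelet grows from 3 at 1 Hz to 10 at 50 Hz (linearly in log
frequency), trading temporal precision at low frequencies for spectral
precision at high ones. Per-trial power is the squared magnitude of the
complex convolution, computed by multiplying the trial's FFT with each
kernel's FFT and inverse-transforming — identical (to float precision) to
direct time-domain convolution but much cheaper.

Normalization: Power(dB) = 10*log10(power_t / power_baseline), with
power_baseline the mean linear power of that trial and frequency over the
whole -2000..+1000 ms epoch. dB maps are therefore invariant to any global
amplitude scaling and to per-frequency gains of the wavelet kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .containers import PROC_RATE_HZ, EpochSet, TFMap, TrialPowerTensor

#: default number of log-spaced wavelet frequencies
DEFAULT_N_FREQS = 50

#: pixels closer than this many Gaussian SDs to an epoch edge are flagged:
#: beyond 2 SDs the kernel energy lost to the zero padding is < 0.25%
#: (< 0.02 dB power bias), inside it the bias grows quickly
EDGE_FLAG_SDS = 2.0


@dataclass
class WaveletBank:
    """Unit-energy complex Morlet kernels on a log-spaced frequency axis."""

    freqs_hz: np.ndarray
    cycles: np.ndarray
    kernels: list  # complex arrays, odd length
    sampling_rate_hz: float

    @property
    def n_freqs(self) -> int:
        return self.freqs_hz.size

    def half_lengths(self) -> np.ndarray:
        return np.array([(k.size - 1) // 2 for k in self.kernels])


def build_wavelet_bank(f_min: float = 1.0, f_max: float = 50.0,
                       n_freqs: int = DEFAULT_N_FREQS, cycle_min: float = 3.0,
                       cycle_max: float = 10.0,
                       rate: float = PROC_RATE_HZ) -> WaveletBank:
    """Log-spaced Morlet bank, cycles interpolated linearly in log frequency.

    Each kernel is a Gaussian-windowed complex exponential truncated at
    +/- 4 Gaussian SDs (8 SDs total) and normalized to unit energy.
    """
    if not (0.0 < f_min < f_max < rate / 2.0):
        raise ValueError("need 0 < f_min < f_max < Nyquist")
    if n_freqs < 2:
        raise ValueError("n_freqs must be >= 2")
    freqs = np.logspace(np.log10(f_min), np.log10(f_max), n_freqs)
    logf = (np.log10(freqs) - np.log10(f_min)) / (np.log10(f_max) - np.log10(f_min))
    cycles = cycle_min + (cycle_max - cycle_min) * logf
    kernels = []
    for f, c in zip(freqs, cycles):
        sigma_t = c / (2.0 * np.pi * f)  # Gaussian SD in seconds
        half = int(np.ceil(4.0 * sigma_t * rate))
        t = np.arange(-half, half + 1) / rate
        k = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
        k /= np.sqrt(np.sum(np.abs(k) ** 2))
        kernels.append(k)
    return WaveletBank(freqs, cycles, kernels, rate)


def wavelet_power(epochs: EpochSet, bank: WaveletBank,
                  dtype=np.float64) -> TrialPowerTensor:
    """Per-trial instantaneous power by FFT-domain convolution.

    Output is (n_trials, n_channels, n_freqs, n_times) linear power, 'same'
    alignment (sample i of the output corresponds to sample i of the trial).
    The edge_mask marks (freq, time) pixels within one kernel half-length of
    either epoch edge, where the convolution sees zero padding.
    """
    if epochs.sampling_rate_hz != bank.sampling_rate_hz:
        raise ValueError("epochs and wavelet bank must share a sampling rate")
    n_trials, n_channels, n_times = epochs.data.shape
    halves = bank.half_lengths()
    max_half = int(halves.max())
    n_conv = n_times + 2 * max_half
    nfft = sp_fft.next_fast_len(n_conv, real=False)

    flat = epochs.data.reshape(n_trials * n_channels, n_times)
    data_f = sp_fft.fft(flat, n=nfft, axis=1, workers=-1)

    power = np.empty((n_trials * n_channels, bank.n_freqs, n_times), dtype=dtype)
    for fi, kern in enumerate(bank.kernels):
        half = (kern.size - 1) // 2
        kern_f = sp_fft.fft(kern, n=nfft)
        conv = sp_fft.ifft(data_f * kern_f, axis=1, workers=-1)
        # full convolution index half..half+n_times-1 is 'same' alignment
        seg = conv[:, half:half + n_times]
        power[:, fi, :] = (seg.real ** 2 + seg.imag ** 2)
    power = power.reshape(n_trials, n_channels, bank.n_freqs, n_times)

    edge = np.zeros((bank.n_freqs, n_times), dtype=bool)
    sigmas_t = bank.cycles / (2.0 * np.pi * bank.freqs_hz)
    for fi, sig in enumerate(sigmas_t):
        h = int(min(np.ceil(EDGE_FLAG_SDS * sig * bank.sampling_rate_hz), n_times))
        edge[fi, :h] = True
        edge[fi, n_times - h:] = True
    return TrialPowerTensor(power, bank.freqs_hz.copy(), epochs.times_ms.copy(),
                            epochs.tasks.copy(), list(epochs.channels),
                            epochs.participant_id, epochs.hemisphere,
                            kind="linear", edge_mask=edge)


def db_normalize(tensor: TrialPowerTensor, baseline_window_ms=None) -> TrialPowerTensor:
    """dB-normalize each trial x channel x frequency against its own baseline.

    baseline_window_ms defaults to the full epoch. By construction the mean
    of 10^(dB/10) over the baseline window is exactly 1 for every trial,
    channel and frequency.
    """
    if tensor.kind != "linear":
        raise ValueError("db_normalize expects a linear-power tensor")
    t = tensor.times_ms
    if baseline_window_ms is None:
        keep = np.ones(t.size, dtype=bool)
    else:
        keep = (t >= baseline_window_ms[0]) & (t <= baseline_window_ms[1])
    baseline = tensor.power[..., keep].mean(axis=-1, keepdims=True)
    if np.any(baseline <= 0):
        bad = np.argwhere(baseline[..., 0] <= 0)[0]
        raise ValueError(
            f"zero baseline power at trial {bad[0]}, channel {bad[1]}, "
            f"frequency index {bad[2]}")
    db = 10.0 * np.log10(tensor.power / baseline)
    return TrialPowerTensor(db, tensor.freqs_hz, tensor.times_ms, tensor.tasks,
                            list(tensor.channels), tensor.participant_id,
                            tensor.hemisphere, kind="db",
                            edge_mask=tensor.edge_mask)


def trial_average(tensor: TrialPowerTensor, condition: str | None = None) -> TFMap:
    """Participant-level map: mean dB over trials (optionally one task)."""
    t = tensor if condition is None else tensor.select_task(condition)
    if t.n_trials == 0:
        raise ValueError(f"no trials to average (condition={condition!r})")
    return TFMap(t.power.mean(axis=0), t.freqs_hz, t.times_ms, list(t.channels),
                 level="participant", condition=condition or "all",
                 participant_id=t.participant_id, hemisphere=t.hemisphere,
                 edge_mask=t.edge_mask)


def grand_average(maps: list[TFMap]) -> TFMap:
    """Unweighted mean of participant maps (equal weight per participant)."""
    if not maps:
        raise ValueError("no maps to average")
    ref = maps[0]
    for m in maps[1:]:
        if m.data.shape != ref.data.shape:
            raise ValueError("all maps must share the channel/frequency/time grid")
    return TFMap(np.mean([m.data for m in maps], axis=0), ref.freqs_hz,
                 ref.times_ms, list(ref.channels), level="grand",
                 condition=ref.condition, edge_mask=ref.edge_mask)


def average_maps(obj, level: str = "participant", condition: str | None = None) -> TFMap:
    """Average into a TFMap: trials of a tensor, or a list of participant maps."""
    if level == "participant":
        return trial_average(obj, condition)
    if level == "grand":
        return grand_average(obj)
    raise ValueError("level must be 'participant' or 'grand'")
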