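"""Wavelet bank construction, spectral-vs-direct convolution equivalence,
dB normalization identities and map averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speechlfp import (
    EpochSet,
    TFMap,
    TrialPowerTensor,
    epoch_time_grid,
    grand_average,
    trial_average,
)
from speechlfp.timefreq import build_wavelet_bank, db_normalize, wavelet_power

RATE = 500.0


def make_epochs(data, tasks=None):
    data = np.asarray(data, float)
    n_trials, _, n_times = data.shape
    times = -500.0 + 2.0 * np.arange(n_times) if n_times != 1501 else epoch_time_grid()
    tasks = tasks or ["vowel"] * n_trials
    return EpochSet(data, times, np.array(tasks, dtype=object),
                    [str(i + 1) for i in range(data.shape[1])], "P01", "left", RATE)


class TestWaveletBank:
    def test_endpoints_and_cycle_range(self):
        bank = build_wavelet_bank(n_freqs=50)
        assert bank.freqs_hz[0] == pytest.approx(1.0)
        assert bank.freqs_hz[-1] == pytest.approx(50.0)
        assert bank.cycles[0] == pytest.approx(3.0)
        assert bank.cycles[-1] == pytest.approx(10.0)
        assert (np.diff(bank.freqs_hz) > 0).all()
        assert (np.diff(bank.cycles) > 0).all()
        # log spacing: constant ratio between neighbours
        ratios = bank.freqs_hz[1:] / bank.freqs_hz[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_two_frequency_bank_is_endpoints(self):
        bank = build_wavelet_bank(n_freqs=2)
        np.testing.assert_allclose(bank.freqs_hz, [1.0, 50.0])

    def test_kernels_unit_energy(self):
        bank = build_wavelet_bank(n_freqs=20)
        for k in bank.kernels:
            assert np.sum(np.abs(k) ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            build_wavelet_bank(f_max=300.0)
        with pytest.raises(ValueError):
            build_wavelet_bank(n_freqs=1)


class TestWaveletPower:
    def test_spectral_equals_direct_convolution(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(501)  # 1 s trial
        bank = build_wavelet_bank(n_freqs=12)
        tensor = wavelet_power(make_epochs(x[None, None, :]), bank)
        for fi, k in enumerate(bank.kernels):
            half = (k.size - 1) // 2
            direct = np.abs(np.convolve(x, k, mode="full")[half:half + 501]) ** 2
            rel = np.max(np.abs(direct - tensor.power[0, 0, fi])) / direct.max()
            assert rel <= 1e-6

    def test_sinusoid_peaks_at_nearest_bank_frequency(self):
        t = np.arange(1501) / RATE
        x = np.sin(2 * np.pi * 6.0 * t)
        bank = build_wavelet_bank(n_freqs=50)
        tensor = wavelet_power(make_epochs(x[None, None, :]), bank)
        profile = tensor.power[0, 0, :, 400:1100].mean(axis=1)
        nearest = np.argmin(np.abs(bank.freqs_hz - 6.0))
        assert profile.argmax() == nearest

    def test_zero_input_zero_power(self):
        bank = build_wavelet_bank(n_freqs=5)
        tensor = wavelet_power(make_epochs(np.zeros((2, 1, 1501))), bank)
        assert np.all(tensor.power == 0)

    def test_power_scales_quadratically(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 1, 1501))
        bank = build_wavelet_bank(n_freqs=6)
        p1 = wavelet_power(make_epochs(x), bank).power
        p3 = wavelet_power(make_epochs(3.0 * x), bank).power
        np.testing.assert_allclose(p3, 9.0 * p1, rtol=1e-10)

    def test_burst_localized_in_time_and_frequency(self):
        # 10 Hz burst at t = 0: peak within 1 bin / 1 cycle duration
        times = epoch_time_grid()
        x = np.zeros_like(times)
        burst = np.abs(times) <= 200.0  # 4 cycles of 10 Hz
        x[burst] = np.sin(2 * np.pi * 10.0 * times[burst] / 1000.0)
        bank = build_wavelet_bank(n_freqs=30)
        tensor = wavelet_power(make_epochs(x[None, None, :]), bank)
        fi, ti = np.unravel_index(tensor.power[0, 0].argmax(), tensor.power[0, 0].shape)
        assert abs(np.log2(bank.freqs_hz[fi] / 10.0)) <= np.log2(
            bank.freqs_hz[1] / bank.freqs_hz[0]) * 1.5
        assert abs(times[ti]) <= 100.0  # one cycle of 10 Hz

    def test_edge_mask_flags_epoch_borders(self):
        bank = build_wavelet_bank(n_freqs=10)
        tensor = wavelet_power(make_epochs(np.ones((1, 1, 1501))), bank)
        assert tensor.edge_mask[0, 0] and tensor.edge_mask[0, -1]
        # low frequencies flag more samples than high frequencies
        assert tensor.edge_mask[0].sum() > tensor.edge_mask[-1].sum()
        assert not tensor.edge_mask[-1, 750]


class TestAgainstMneMorlet:
    def test_matches_mne_tfr_array_morlet_up_to_per_frequency_gain(self):
        """Independent cross-check: MNE's Morlet TFR agrees with ours up to a
        per-frequency gain constant (a normalization convention), which the
        dB maps cancel exactly."""
        from mne.time_frequency import tfr_array_morlet

        rng = np.random.default_rng(7)
        data = rng.standard_normal((4, 2, 1501))
        # 4-50 Hz so every kernel fits inside the epoch (MNE requirement)
        bank = build_wavelet_bank(f_min=4.0, n_freqs=10)
        ours_lin = wavelet_power(make_epochs(data), bank)
        ours_db = db_normalize(ours_lin)
        mne_p = tfr_array_morlet(data, RATE, bank.freqs_hz, n_cycles=bank.cycles,
                                 output="power", zero_mean=False)
        interior = slice(400, 1100)  # clear of both implementations' edges
        ratio = ours_lin.power[..., interior] / mne_p[..., interior]
        for fi in range(bank.n_freqs):
            r = ratio[:, :, fi]
            assert r.std() / r.mean() < 0.01  # constant gain per frequency
        mne_db = 10 * np.log10(mne_p / mne_p.mean(axis=-1, keepdims=True))
        diff = np.abs(ours_db.power - mne_db)[..., interior]
        assert np.median(diff) < 0.01
        assert np.quantile(diff, 0.99) < 0.05


class TestDbNormalize:
    def _tensor(self, power, tasks=None):
        power = np.asarray(power, float)
        n_times = power.shape[-1]
        times = epoch_time_grid() if n_times == 1501 else np.arange(n_times) * 2.0
        tasks = tasks or ["vowel"] * power.shape[0]
        return TrialPowerTensor(power, np.logspace(0, np.log10(50), power.shape[2]),
                                times, np.array(tasks, dtype=object),
                                [str(i + 1) for i in range(power.shape[1])],
                                "P01", "left", kind="linear")

    def test_constant_power_maps_to_zero_db(self):
        t = self._tensor(np.full((3, 2, 4, 100), 7.5))
        db = db_normalize(t)
        np.testing.assert_allclose(db.power, 0.0, atol=1e-12)

    def test_tenfold_pixel_is_plus_ten_db(self):
        p = np.ones((1, 1, 1, 1000))
        p[0, 0, 0, 500] = 10.0
        db = db_normalize(self._tensor(p)).power[0, 0, 0]
        baseline_db = 10 * np.log10(np.mean(p))
        assert db[500] - db[499] == pytest.approx(10.0, abs=1e-9)
        assert db[500] == pytest.approx(10.0 - baseline_db, abs=1e-9)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_global_scaling_invariance(self, scale):
        rng = np.random.default_rng(4)
        p = rng.exponential(size=(2, 1, 3, 50))
        db1 = db_normalize(self._tensor(p)).power
        db2 = db_normalize(self._tensor(scale * p)).power
        np.testing.assert_allclose(db1, db2, atol=1e-9)

    def test_baseline_reconstructs_to_unity(self):
        rng = np.random.default_rng(5)
        p = rng.exponential(size=(4, 2, 3, 1501))
        db = db_normalize(self._tensor(p))
        recon = (10.0 ** (db.power / 10.0)).mean(axis=-1)
        np.testing.assert_allclose(recon, 1.0, atol=1e-12)

    def test_zero_baseline_names_offender(self):
        p = np.ones((2, 1, 2, 10))
        p[1, 0, 1] = 0.0
        with pytest.raises(ValueError, match="trial 1"):
            db_normalize(self._tensor(p))


class TestAveraging:
    def _map(self, value, pid="P01"):
        return TFMap(np.full((4, 3, 10), float(value)), np.array([1.0, 5.0, 20.0]),
                     np.arange(10.0), ["1", "2", "3", "4"], participant_id=pid)

    def test_single_trial_average_is_that_trial(self):
        rng = np.random.default_rng(6)
        p = rng.standard_normal((1, 4, 3, 10))
        t = TrialPowerTensor(p, np.array([1.0, 5.0, 20.0]), np.arange(10.0),
                             np.array(["ddk"], dtype=object), ["1", "2", "3", "4"],
                             "P01", "left", kind="db")
        np.testing.assert_allclose(trial_average(t, "ddk").data, p[0])

    def test_grand_average_is_unweighted(self):
        g = grand_average([self._map(1.0), self._map(-1.0)])
        np.testing.assert_allclose(g.data, 0.0)
        assert g.level == "grand"

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            grand_average([])
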