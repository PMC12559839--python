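"""Surrogate null construction, p-value counting, thresholding, contrasts."""

import numpy as np
import pytest

from speechlfp import (
    EpochSet,
    TFMap,
    TrialPowerTensor,
    build_null,
    contrast,
    epoch_time_grid,
    pink_noise,
    pixel_p,
    pool_nulls,
    threshold,
    trial_average,
    within_condition,
)
from speechlfp.synth import inject_modulation
from speechlfp.timefreq import build_wavelet_bank, db_normalize, wavelet_power

RATE = 500.0


def make_db_tensor(values, tasks=None, pid="P01"):
    values = np.asarray(values, float)
    n_trials, _, n_freqs, n_times = values.shape
    times = epoch_time_grid() if n_times == 1501 else np.arange(n_times) * 2.0 - 2000.0
    tasks = tasks or ["vowel"] * n_trials
    return TrialPowerTensor(values, np.logspace(0, np.log10(50), n_freqs), times,
                            np.array(tasks, dtype=object),
                            [str(i + 1) for i in range(values.shape[1])],
                            pid, "left", kind="db")


class TestBuildNull:
    def test_constant_tensor_gives_constant_null(self):
        t = make_db_tensor(np.full((5, 1, 3, 1501), 2.5))
        null = build_null(t, seed=0)
        np.testing.assert_allclose(null.values, 2.5)

    def test_shuffle_count(self):
        t = make_db_tensor(np.random.default_rng(0).standard_normal((5, 1, 3, 1501)))
        null = build_null(t, n_shuffles=300, seed=0)
        assert null.values.shape == (300, 1, 3)

    def test_clt_scaling_of_null_sd(self):
        rng = np.random.default_rng(1)
        t = make_db_tensor(rng.standard_normal((40, 2, 4, 1501)))
        null = build_null(t, n_shuffles=2241, seed=2)
        sds = null.values.std(axis=0)
        np.testing.assert_allclose(sds, 1 / np.sqrt(40), rtol=0.20)

    def test_draws_come_from_baseline_window_only(self):
        vals = np.zeros((10, 1, 1, 1501))
        times = epoch_time_grid()
        vals[..., (times > -1000) & (times <= -500)] = 5.0
        null = build_null(make_db_tensor(vals), n_shuffles=250, seed=3)
        np.testing.assert_allclose(null.values, 5.0)

    def test_warning_below_resolution_and_error_below_minimum(self):
        t = make_db_tensor(np.random.default_rng(2).standard_normal((5, 1, 2, 1501)))
        with pytest.warns(UserWarning, match="cannot resolve"):
            build_null(t, n_shuffles=500, seed=1)
        with pytest.raises(ValueError):
            build_null(t, n_shuffles=100, seed=1)

    def test_seed_reproducibility(self):
        t = make_db_tensor(np.random.default_rng(3).standard_normal((8, 1, 2, 1501)))
        n1 = build_null(t, n_shuffles=300, seed=9)
        n2 = build_null(t, n_shuffles=300, seed=9)
        assert np.array_equal(n1.values, n2.values)


class TestPixelP:
    def _null(self, values):
        return build_null(make_db_tensor(values), n_shuffles=2241, seed=0)

    def test_extreme_observation_smallest_p(self):
        rng = np.random.default_rng(4)
        null = self._null(rng.standard_normal((20, 1, 1, 1501)))
        obs = TFMap(np.full((1, 1, 3), -99.0), null.freqs_hz,
                    np.array([0.0, 2.0, 4.0]), ["1"])
        p = pixel_p(obs, null)
        np.testing.assert_allclose(p, 2.0 / 2242.0)
        assert p[0, 0, 0] < 0.001

    def test_median_observation_near_one(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((20, 1, 1, 1501))
        null = self._null(vals)
        med = float(np.median(null.values[:, 0, 0]))
        obs = TFMap(np.full((1, 1, 1), med), null.freqs_hz, np.array([0.0]), ["1"])
        assert pixel_p(obs, null)[0, 0, 0] > 0.9

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(6)
        null = self._null(rng.standard_normal((20, 1, 2, 1501)))
        obs = TFMap(rng.standard_normal((1, 2, 100)), null.freqs_hz,
                    np.arange(100.0), ["1"])
        p = pixel_p(obs, null)
        assert (p > 0).all() and (p <= 1).all()


class TestThreshold:
    def test_alpha_one_marks_all_valid_pixels(self):
        rng = np.random.default_rng(7)
        t = make_db_tensor(rng.standard_normal((10, 1, 2, 1501)))
        null = build_null(t, n_shuffles=300, seed=0)
        obs = trial_average(t)
        res = threshold(obs, null, alpha=1.1)
        assert np.array_equal(res.mask, res.valid)
        # evaluation restricted to -500..+1000 ms
        in_window = (obs.times_ms >= -500) & (obs.times_ms <= 1000)
        assert not res.mask[:, :, ~in_window].any()

    def test_iid_pixels_calibrate_at_alpha(self):
        """With many independent baseline samples per trial the empirical
        rejection rate matches the nominal level."""
        rng = np.random.default_rng(8)
        tensors = [make_db_tensor(rng.standard_normal((30, 2, 6, 1501)),
                                  pid=f"P{p}") for p in range(5)]
        res = within_condition(tensors, "vowel", seed=11)
        rate = res.mask.sum() / res.valid.sum()
        assert rate <= 0.004

    def test_edge_flagged_pixels_never_significant(self):
        rng = np.random.default_rng(9)
        epochs = EpochSet(rng.standard_normal((12, 1, 1501)), epoch_time_grid(),
                          np.array(["vowel"] * 12, dtype=object), ["1"],
                          "P01", "left", RATE)
        tensor = db_normalize(wavelet_power(epochs, build_wavelet_bank(n_freqs=8)))
        null = build_null(tensor, n_shuffles=300, seed=1)
        res = threshold(trial_average(tensor), null, alpha=1.1)
        assert not (res.mask & tensor.edge_mask[None]).any()


class TestMonotonicity:
    def test_larger_injected_effect_never_fewer_significant_pixels(self):
        """Significant theta pixel counts are non-decreasing in effect size."""
        rng = np.random.default_rng(10)
        n = int(260 * RATE)
        base = pink_noise(n, 1.0, RATE, seed=12)
        onsets = np.arange(5.0, 250.0, 2.8)
        counts = []
        bank = build_wavelet_bank(n_freqs=10)
        for effect_db in (0.0, 3.0, 6.0):
            x = inject_modulation(base, (1, 8), (0, 1000), effect_db, onsets, RATE)
            trials = np.stack([
                x[int((o - 2.0) * RATE): int((o - 2.0) * RATE) + 1501]
                for o in onsets])
            epochs = EpochSet(trials[:, None, :], epoch_time_grid(),
                              np.array(["vowel"] * len(onsets), dtype=object),
                              ["1"], "P01", "left", RATE)
            tensor = db_normalize(wavelet_power(epochs, bank))
            null = build_null(tensor, seed=13)
            res = threshold(trial_average(tensor), null)
            theta = tensor.freqs_hz <= 8.0
            during = (tensor.times_ms >= 0) & (tensor.times_ms <= 1000)
            counts.append(int(res.mask[:, theta][:, :, during].sum()))
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > counts[0]


class TestContrast:
    def _paired_tensors(self, rng, offset=0.0):
        a = [make_db_tensor(rng.standard_normal((15, 1, 3, 1501)) + offset,
                            pid=f"P{p}") for p in range(3)]
        return a

    def test_identical_conditions_yield_no_significance(self):
        rng = np.random.default_rng(11)
        a = self._paired_tensors(rng)
        res = contrast(a, a, n_shuffles=2241, seed=14)
        np.testing.assert_allclose(res.map.data, 0.0, atol=1e-12)
        assert res.mask.sum() == 0

    def test_antisymmetry_of_difference_map(self):
        rng = np.random.default_rng(12)
        a = self._paired_tensors(rng)
        b = [make_db_tensor(rng.standard_normal((15, 1, 3, 1501)), pid=f"P{p}")
             for p in range(3)]
        r_ab = contrast(a, b, n_shuffles=300, seed=15)
        r_ba = contrast(b, a, n_shuffles=300, seed=15)
        np.testing.assert_allclose(r_ab.map.data, -r_ba.map.data, atol=1e-12)

    def test_mismatched_participants_rejected(self):
        rng = np.random.default_rng(13)
        a = self._paired_tensors(rng)
        with pytest.raises(ValueError):
            contrast(a, a[:2], n_shuffles=300, seed=0)
        b = [make_db_tensor(rng.standard_normal((15, 1, 3, 1501)), pid="PX")
             for _ in range(3)]
        with pytest.raises(ValueError):
            contrast(a, b, n_shuffles=300, seed=0)


class TestPoolNulls:
    def test_pooled_null_is_elementwise_mean(self):
        rng = np.random.default_rng(14)
        t1 = make_db_tensor(rng.standard_normal((10, 1, 2, 1501)), pid="P1")
        t2 = make_db_tensor(rng.standard_normal((10, 1, 2, 1501)), pid="P2")
        n1 = build_null(t1, n_shuffles=300, seed=1)
        n2 = build_null(t2, n_shuffles=300, seed=2)
        pooled = pool_nulls([n1, n2])
        np.testing.assert_allclose(pooled.values, (n1.values + n2.values) / 2)
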