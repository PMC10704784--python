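import numpy as np
import pytest

from lctcc import sync as sy
from lctcc.types import EventSeries, UniformSignal, ValidationError


def _sine(freq, fs=50.0, dur=120.0, amp=1.0, offset=0.0):
    t = np.arange(int(dur * fs)) / fs
    return UniformSignal(offset + amp * np.sin(2 * np.pi * freq * t), fs, kind="rate")


def _band_noise(n, fs, low, high, seed):
    """Brick-wall band-limited unit-variance noise (test helper)."""
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


class TestDeltaPowerRatio:
    def test_in_band_tone_near_one(self):
        assert sy.delta_power_ratio(_sine(1.0)) > 0.95

    def test_out_of_band_tone_near_zero(self):
        assert sy.delta_power_ratio(_sine(5.0)) < 0.05

    def test_scale_and_offset_invariant(self):
        a = sy.delta_power_ratio(_sine(1.0, amp=1.0))
        b = sy.delta_power_ratio(_sine(1.0, amp=20.0, offset=100.0))
        assert a == pytest.approx(b, rel=1e-9)

    def test_white_noise_matches_bandwidth_fraction(self):
        # flat PSD: expected ratio = (2 - 0.3) / 25
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sig = UniformSignal(rng.standard_normal(50 * 240), 50.0, kind="rate")
            ratios.append(sy.delta_power_ratio(sig))
        expected = (2.0 - 0.3) / 25.0
        assert np.mean(ratios) == pytest.approx(expected, rel=0.5)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValidationError, match="delta cycles"):
            sy.delta_power_ratio(_sine(1.0, dur=20.0))

    def test_low_fs_rejected(self):
        with pytest.raises(ValidationError):
            sy.delta_power_ratio(_sine(1.0, fs=2.0, dur=120.0))


class TestSyncIndex:
    def _stim(self, starts, n=50, isi=2.0):
        return [
            EventSeries(s + np.arange(n) * isi, 0.005, isi, "meningeal") for s in starts
        ]

    def test_windows_lie_between_trains(self):
        rate = _sine(1.0, fs=50.0, dur=1700.0, offset=5.0)
        res = sy.sync_index(rate, self._stim([30.0, 770.0, 1510.0]))
        assert res.value > 0.9
        assert len(res.windows) == 2
        gaps = [(130.0, 770.0), (870.0, 1510.0)]
        for (w0, w1), (g0, g1) in zip(res.windows, gaps):
            assert g0 <= w0 < w1 <= g1
            assert (w1 - w0) == pytest.approx(600.0)

    def test_needs_two_usable_gaps(self):
        rate = _sine(1.0, fs=50.0, dur=600.0)
        with pytest.raises(ValidationError, match="gaps"):
            sy.sync_index(rate, self._stim([30.0, 400.0]))

    def test_constant_rate_flagged_degenerate(self):
        rate = UniformSignal(np.full(50 * 1700, 4.0), 50.0, kind="rate")
        res = sy.sync_index(rate, self._stim([30.0, 770.0, 1510.0]))
        assert res.degenerate and res.value == 0.0


class TestDecimate:
    def test_slow_tone_preserved(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        lfp = UniformSignal(np.sin(2 * np.pi * 1.0 * t), fs, kind="lfp_raw")
        out = sy.decimate_lfp(lfp)
        assert out.fs == 50.0
        ref = np.sin(2 * np.pi * 1.0 * out.times())
        interior = slice(50, -50)
        assert np.corrcoef(out.values[interior], ref[interior])[0, 1] > 0.999
        assert out.values[interior].std() == pytest.approx(ref[interior].std(), rel=0.02)

    def test_above_nyquist_tone_attenuated(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        lfp = UniformSignal(np.sin(2 * np.pi * 40.0 * t), fs, kind="lfp_raw")
        out = sy.decimate_lfp(lfp)
        assert out.values.std() < 0.05 * lfp.values.std()

    def test_zero_group_delay(self):
        fs = 1000.0
        x = np.zeros(int(30 * fs))
        x[int(10.0 * fs)] = 1.0
        out = sy.decimate_lfp(UniformSignal(x, fs, kind="lfp_raw"))
        t_peak = out.times()[np.argmax(np.abs(out.values))]
        assert t_peak == pytest.approx(10.0, abs=1.0 / 50.0)

    def test_non_integer_ratio_supported(self):
        fs = 325.0
        t = np.arange(int(40 * fs)) / fs
        out = sy.decimate_lfp(UniformSignal(np.sin(2 * np.pi * t), fs, kind="lfp_raw"))
        assert out.fs == 50.0
        ref = np.sin(2 * np.pi * out.times())
        assert np.corrcoef(out.values[100:-100], ref[100:-100])[0, 1] > 0.99

    def test_low_input_rate_rejected(self):
        with pytest.raises(ValidationError):
            sy.decimate_lfp(UniformSignal(np.zeros(100), 80.0, kind="lfp_raw"))


class TestSpectrogram:
    def _spec_of_tone(self, freq, dur=120.0):
        t = np.arange(int(dur * 50.0)) / 50.0
        sig = UniformSignal(np.sin(2 * np.pi * freq * t), 50.0, kind="lfp_decimated")
        return sy.spectrogram(sig)

    def test_protocol_parameters(self):
        spec = self._spec_of_tone(1.0)
        assert spec.frame_fs == pytest.approx(5.0)  # hop of 10 samples at 50 Hz
        assert np.diff(spec.freqs)[0] == pytest.approx(50.0 / 8096)
        assert spec.log_psd.shape == (len(spec.freqs), len(spec.times))

    def test_tone_ridge_at_right_frequency(self):
        spec = self._spec_of_tone(1.3)
        ridge = spec.freqs[np.argmax(spec.log_psd.mean(axis=1))]
        assert ridge == pytest.approx(1.3, abs=0.05)

    def test_requires_50hz_input(self):
        sig = UniformSignal(np.zeros(10000), 100.0, kind="lfp_raw")
        with pytest.raises(ValidationError):
            sy.spectrogram(sig)

    def test_requires_enough_samples(self):
        sig = UniformSignal(np.zeros(500), 50.0, kind="lfp_decimated")
        with pytest.raises(ValidationError):
            sy.spectrogram(sig)


class TestDeltaTimecourse:
    def test_tracks_amplitude_modulation(self):
        fs, dur = 200.0, 1200.0
        n = int(dur * fs)
        t = np.arange(n) / fs
        env = 1.5 + np.cos(2 * np.pi * t / 200.0)
        x = _band_noise(n, fs, 0.3, 2.0, seed=1) * env
        tc = sy.delta_band_timecourse(
            sy.spectrogram(sy.decimate_lfp(UniformSignal(x, fs, kind="lfp_raw")))
        )
        ref = 1.5 + np.cos(2 * np.pi * tc.times() / 200.0)
        assert np.corrcoef(tc.values, ref)[0, 1] > 0.8

    def test_flat_noise_gives_flatter_timecourse(self):
        fs, dur = 200.0, 600.0
        n = int(dur * fs)
        t = np.arange(n) / fs
        flat = _band_noise(n, fs, 0.3, 2.0, seed=2)
        mod = flat * (1.5 + np.cos(2 * np.pi * t / 150.0))
        sd = {
            name: sy.delta_band_timecourse(
                sy.spectrogram(sy.decimate_lfp(UniformSignal(x, fs, kind="lfp_raw")))
            ).values.std()
            for name, x in (("flat", flat), ("mod", mod))
        }
        assert sd["mod"] > 3 * sd["flat"]


class TestSlidingR2:
    def _grid_signal(self, values, fs, kind="band_power"):
        return UniformSignal(values, fs, kind=kind)

    def test_identical_inputs_give_r2_one(self):
        t = np.arange(0, 1200, 0.5)
        x = np.sin(2 * np.pi * t / 300.0) + 0.1 * np.cos(2 * np.pi * t / 90.0)
        res = sy.sliding_r2(self._grid_signal(x, 2.0), self._grid_signal(x, 2.0, "rate"))
        assert res["r2max"] == pytest.approx(1.0, abs=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2400)
        y = rng.standard_normal(2400)
        a = sy.sliding_r2(self._grid_signal(x, 2.0), self._grid_signal(y, 2.0, "rate"))
        b = sy.sliding_r2(
            self._grid_signal(5.0 - 3.0 * x, 2.0), self._grid_signal(2.0 * y + 7, 2.0, "rate")
        )
        np.testing.assert_allclose(
            a["r2_series"].values, b["r2_series"].values, atol=1e-9
        )

    def test_coupled_beats_uncoupled(self):
        t = np.arange(0, 1200, 0.5)
        rng = np.random.default_rng(1)
        slow = np.sin(2 * np.pi * t / 300.0)
        coupled = slow + 0.2 * rng.standard_normal(t.size)
        uncoupled = np.sin(2 * np.pi * t / 77.0)
        r_c = sy.sliding_r2(self._grid_signal(coupled, 2.0), self._grid_signal(slow, 2.0, "rate"))
        r_u = sy.sliding_r2(self._grid_signal(uncoupled, 2.0), self._grid_signal(slow, 2.0, "rate"))
        assert r_c["r2max"] > 0.9
        assert r_u["r2max"] < r_c["r2max"]

    def test_needs_400s_overlap(self):
        x = np.zeros(300)
        with pytest.raises(ValidationError):
            sy.sliding_r2(self._grid_signal(x, 1.0), self._grid_signal(x, 1.0, "rate"))


class TestCrossCorrelogramLag:
    def test_zero_lag_for_identical_signals(self):
        x = _band_noise(60000, 1000.0, 0.3, 2.0, seed=3)
        sig = UniformSignal(x, 1000.0, kind="lfp_raw")
        assert abs(sy.crosscorrelogram_lag(sig, sig)) < 1e-3

    def test_known_shift_recovered(self):
        fs = 1000.0
        x = _band_noise(int(600 * fs), fs, 0.3, 2.0, seed=4)
        t = np.arange(x.size) / fs
        delayed = np.interp(t - 0.010, t, x)
        lag = sy.crosscorrelogram_lag(
            UniformSignal(x, fs, kind="lfp_raw"), UniformSignal(delayed, fs, kind="lfp_raw")
        )
        assert lag == pytest.approx(0.010, abs=0.001)

    def test_antisymmetric_under_swap(self):
        fs = 1000.0
        x = _band_noise(int(120 * fs), fs, 0.3, 2.0, seed=5)
        t = np.arange(x.size) / fs
        y = np.interp(t - 0.008, t, x) + 0.1 * _band_noise(x.size, fs, 0.3, 2.0, seed=6)
        a = UniformSignal(x, fs, kind="lfp_raw")
        b = UniformSignal(y, fs, kind="lfp_raw")
        assert sy.crosscorrelogram_lag(a, b) == pytest.approx(
            -sy.crosscorrelogram_lag(b, a), abs=1e-6
        )

    def test_constant_signal_rejected(self):
        a = UniformSignal(np.zeros(1000), 1000.0, kind="lfp_raw")
        with pytest.raises(ValidationError, match="constant"):
            sy.crosscorrelogram_lag(a, a)

    def test_mismatched_sampling_rejected(self):
        a = UniformSignal(np.random.default_rng(0).standard_normal(1000), 1000.0, kind="lfp_raw")
        b = UniformSignal(a.values, 500.0, kind="lfp_raw")
        with pytest.raises(ValidationError):
            sy.crosscorrelogram_lag(a, b)
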