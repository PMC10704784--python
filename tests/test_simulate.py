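import numpy as np
import pytest
from scipy import stats as sst
from scipy.integrate import cumulative_trapezoid

from lctcc import simulate as sim
from lctcc.types import EventSeries, SpikeTrain, UniformSignal, ValidationError


class TestPresets:
    def test_naive_injects_observed_parameters(self):
        cfg = sim.preset("naive")
        assert cfg.coupling_lag == pytest.approx(0.0101)
        periods = {r.name: r.period for r in cfg.rhythms["LC"]}
        assert periods["slow"] == pytest.approx(400.4)
        assert periods["intermediate"] == pytest.approx(21.3)
        lats = [c.peak_latency for c in cfg.evoked["LC"].components]
        assert lats == pytest.approx([0.0628, 0.1296])

    def test_sensitized_shifts_periods_and_phase(self):
        cfg = sim.preset("sensitized")
        periods = {r.name: r.period for r in cfg.rhythms["TCC"]}
        assert periods["slow"] == pytest.approx(675.0)
        assert periods["intermediate"] == pytest.approx(20.5)
        assert cfg.tcc_phase_advance > 0
        assert cfg.base_rate["TCC"] > sim.preset("naive").base_rate["TCC"]

    def test_propranolol_damps_lc_delta_and_evoked(self):
        naive, prop = sim.preset("naive"), sim.preset("propranolol")
        depth = lambda c, n: next(r.depth for r in c.rhythms["LC"] if r.name == n)  # noqa: E731
        assert depth(prop, "delta") < depth(naive, "delta")
        assert (prop.evoked["LC"].components[0].gain
                < naive.evoked["LC"].components[0].gain)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            sim.preset("martian")

    def test_config_dict_round_trip(self):
        cfg = sim.preset("sensitized", seed=3, duration=50.0)
        back = sim.GeneratorConfig.from_dict(cfg.to_dict())
        assert back.to_dict() == cfg.to_dict()


class TestRateProcess:
    def test_zero_depth_gives_constant_base_rate(self):
        cfg = sim.GeneratorConfig(duration=20.0, rhythms={
            "LC": [sim.RhythmSpec(period=5.0, depth=0.0)]})
        rate = sim.rate_process(cfg, "LC")
        np.testing.assert_allclose(rate.values, 12.0)

    def test_mean_rate_conserved_over_whole_cycles(self):
        cfg = sim.GeneratorConfig(
            duration=600.0, shared_fraction=1.0,
            rhythms={"LC": [sim.RhythmSpec(period=2.0, depth=0.5, name="delta")]},
        )
        rate = sim.rate_process(cfg, "LC")
        assert rate.values.mean() == pytest.approx(12.0, rel=0.01)
        assert rate.values.min() >= 0.0

    def test_tcc_shared_rhythm_is_delayed_copy(self):
        cfg = sim.GeneratorConfig(
            duration=100.0, base_rate={"LC": 10.0, "TCC": 10.0},
            shared_fraction=1.0, coupling_lag=0.1, fs_rate=100.0,
            rhythms={r: [sim.RhythmSpec(period=2.0, depth=0.5, name="delta")]
                     for r in ("LC", "TCC")},
        )
        lc = sim.rate_process(cfg, "LC").values
        tcc = sim.rate_process(cfg, "TCC").values
        shift = int(round(0.1 * 100.0))  # lag in samples
        np.testing.assert_allclose(tcc[shift:], lc[:-shift], atol=1e-9)

    def test_deterministic_across_calls(self):
        cfg = sim.preset("naive", seed=11, duration=30.0)
        a = sim.rate_process(cfg, "TCC").values
        b = sim.rate_process(sim.preset("naive", seed=11, duration=30.0), "TCC").values
        np.testing.assert_array_equal(a, b)


class TestSampleSpikes:
    def test_zero_rate_gives_empty_train(self):
        rate = UniformSignal(np.zeros(100), 10.0, kind="rate")
        assert len(sim.sample_spikes(rate, seed=1)) == 0

    def test_poisson_count_oracle_constant_rate(self):
        rate = UniformSignal(np.full(1000, 10.0), 10.0, kind="rate")  # 10 Hz, 100 s
        counts = [len(sim.sample_spikes(rate, seed=s)) for s in range(20)]
        # mean of 20 Poisson(1000) draws: sd of the mean ~ sqrt(1000/20) ~ 7.1
        assert abs(np.mean(counts) - 1000.0) < 5 * np.sqrt(1000 / 20)

    def test_time_rescaling_uniformity(self):
        """Rescaled inter-spike intervals of an inhomogeneous Poisson train
        are Exp(1) (Brown et al. time-rescaling theorem)."""
        fs, dur = 100.0, 300.0
        t = np.arange(int(dur * fs)) / fs
        lam = 5.0 * (1.0 + 0.8 * np.cos(2 * np.pi * t / 2.0))
        rate = UniformSignal(lam, fs, kind="rate")
        train = sim.sample_spikes(rate, seed=42)
        cum = np.r_[0.0, cumulative_trapezoid(lam, t)]
        rescaled = np.interp(train.times, t, cum)
        u = 1.0 - np.exp(-np.diff(rescaled))
        p = sst.kstest(u, "uniform").pvalue
        assert p > 0.005

    def test_rejects_non_rate_signal(self):
        with pytest.raises(ValidationError):
            sim.sample_spikes(UniformSignal(np.zeros(10), 1.0, kind="lfp_raw"), 0)


class TestAddEvoked:
    def _events(self, n=200):
        return EventSeries(5.0 + np.arange(n) * 2.0, 0.005, 2.0, "meningeal")

    def test_expected_extra_spikes_matches_gain(self):
        spec = sim.EvokedSpec(components=[sim.EvokedComponentSpec(0.0628, 0.010, 3.0)])
        base = SpikeTrain([], "LC", "MUA", "u")
        out = sim.add_evoked(base, self._events(), spec, seed=5)
        expected = 3.0 * 200
        assert abs(len(out) - expected) < 5 * np.sqrt(expected)

    def test_latencies_cluster_at_configured_peak(self):
        spec = sim.EvokedSpec(components=[sim.EvokedComponentSpec(0.0628, 0.010, 5.0)])
        ev = self._events()
        out = sim.add_evoked(SpikeTrain([], "LC", "MUA", "u"), ev, spec, seed=9)
        offsets = (out.times - ev.onsets[0]) % 2.0
        assert np.median(offsets) == pytest.approx(0.0628, abs=0.002)

    def test_original_spikes_retained_and_zero_gain_is_identity(self):
        base = SpikeTrain([1.0, 2.5, 7.25], "LC", "MUA", "u")
        spec = sim.EvokedSpec(components=[sim.EvokedComponentSpec(0.05, 0.01, 0.0)])
        out = sim.add_evoked(base, self._events(5), spec, seed=0)
        np.testing.assert_array_equal(out.times, base.times)

    def test_component_beyond_isi_rejected(self):
        spec = sim.EvokedSpec(components=[sim.EvokedComponentSpec(1.99, 0.05, 1.0)])
        with pytest.raises(ValidationError):
            sim.add_evoked(SpikeTrain([], "LC", "MUA", "u"), self._events(5), spec, 0)


class TestMakeLfp:
    def test_tcc_is_delayed_lc_when_noiseless(self):
        cfg = sim.preset("naive", seed=3, duration=30.0)
        cfg.lfp_noise_sd = 0.0
        cfg.coupling_lag = 0.02
        lc = sim.make_lfp(cfg, "LC")
        tcc = sim.make_lfp(cfg, "TCC")
        shift = int(round(0.02 * cfg.fs_lfp))
        np.testing.assert_allclose(tcc.values[shift:], lc.values[:-shift], atol=1e-6)

    def test_spectrum_confined_to_delta_band(self):
        cfg = sim.preset("naive", seed=3, duration=120.0)
        cfg.lfp_noise_sd = 0.0
        lfp = sim.make_lfp(cfg, "LC")
        from scipy.signal import periodogram

        freqs, psd = periodogram(lfp.values, fs=cfg.fs_lfp)
        band = (freqs >= 0.29) & (freqs <= 2.01)
        # envelope modulation by the slow rhythms widens the band only
        # marginally; >90% of power stays in 0.3-2 Hz
        assert np.trapezoid(psd[band], freqs[band]) > 0.9 * np.trapezoid(psd, freqs)


class TestGenerateSession:
    def test_bit_identical_for_identical_config(self):
        a = sim.generate_session(sim.preset("naive", seed=21, duration=60.0))
        b = sim.generate_session(sim.preset("naive", seed=21, duration=60.0))
        for ta, tb in zip(a.spike_trains, b.spike_trains):
            np.testing.assert_array_equal(ta.times, tb.times)
        np.testing.assert_array_equal(a.lfp["LC"].values, b.lfp["LC"].values)

    def test_seed_changes_spikes(self):
        a = sim.generate_session(sim.preset("naive", seed=1, duration=60.0))
        b = sim.generate_session(sim.preset("naive", seed=2, duration=60.0))
        assert len(a.trains("LC")[0]) != len(b.trains("LC")[0]) or not np.array_equal(
            a.trains("LC")[0].times, b.trains("LC")[0].times
        )

    def test_session_structure(self, naive_session):
        s = naive_session
        assert s.condition == "naive"
        assert {t.region for t in s.spike_trains} == {"LC", "TCC"}
        assert s.trains("LC", "MUA") and s.trains("TCC", "SU")
        assert len(s.events) == 3 and all(e.label == "meningeal" for e in s.events)
        for tr in s.spike_trains:
            assert tr.times[0] >= 0 and tr.times[-1] <= s.duration
        assert s.ground_truth["coupling_lag"] == pytest.approx(0.0101)
        assert s.lfp["LC"].values.size == int(s.duration * s.ground_truth["fs_lfp"])

    def test_short_session_gets_single_train(self):
        s = sim.generate_session(sim.preset("naive", seed=0, duration=200.0))
        assert len(s.events) == 1
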