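"""Synthetic two-region session generator with ground truth.

The generator emulates the statistical structure the coupling analysis
assumes: a multi-timescale oscillatory drive shared between the locus
coeruleus (LC) and the trigeminocervical complex (TCC) — a slow rhythm
(period of order hundreds of seconds), an intermediate rhythm (~20 s) and
a delta rhythm (0.3–2 Hz) — with the TCC copy of the shared drive delayed
by a directed LC->TCC lag of order 10 ms, stimulus-locked evoked
components with region-specific latencies, and condition presets (naive /
sensitized / propranolol) that alter baseline rate, evoked magnitudes,
phase relationships and delta synchrony.

Spiking is an inhomogeneous Poisson process sampled by thinning; the LC
multi-unit record is the union of several independently thinned trains
from the same rate, mirroring multi-unit extraction.  Every session
carries its generator parameters as ``ground_truth``.
"""

from __future__ import annotations

import copy
import math
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np

from .types import (
    EventSeries,
    PROTOCOL_CUTANEOUS,
    PROTOCOL_MENINGEAL,
    Session,
    SpikeTrain,
    UniformSignal,
    ValidationError,
    canonical_region,
)

__all__ = [
    "RhythmSpec",
    "EvokedSpec",
    "GeneratorConfig",
    "preset",
    "rate_process",
    "sample_spikes",
    "add_evoked",
    "make_lfp",
    "generate_session",
]

# Observed rhythm periods (s) injected by the presets.
NAIVE_SLOW_PERIOD = 400.4
NAIVE_INTERMEDIATE_PERIOD = 21.3
SENSITIZED_SLOW_PERIOD = 675.0
SENSITIZED_INTERMEDIATE_PERIOD = 20.5
# Directed LC->TCC conduction/integration delay (s), naive condition.
NAIVE_COUPLING_LAG = 0.0101
# LC evoked component latencies (s), dural stimulation.
LC_EARLY_LATENCY = 0.0628
LC_LATE_LATENCY = 0.1296

DELTA_BAND = (0.3, 2.0)


@dataclass
class RhythmSpec:
    """One multiplicative cosine modulation of the firing rate."""

    period: float
    depth: float
    phase0: float = 0.0
    name: str = ""

    def __post_init__(self):
        if not self.period > 0:
            raise ValidationError("rhythm period must be positive")
        if not 0.0 <= self.depth <= 1.0:
            raise ValidationError("rhythm depth must lie in [0, 1]")


FWHM_TO_SD = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class EvokedComponentSpec:
    """One Gaussian bump of stimulus-locked extra rate.

    ``gain`` is the expected number of extra spikes per stimulus (the
    integral of the bump); ``width`` is the bump's full width at half
    maximum (FWHM).
    """

    peak_latency: float
    width: float
    gain: float

    def __post_init__(self):
        if self.peak_latency <= 0 or self.width <= 0 or self.gain < 0:
            raise ValidationError("evoked component needs latency, width > 0 and gain >= 0")


@dataclass
class EvokedSpec:
    components: list = field(default_factory=list)

    def __post_init__(self):
        self.components = [
            c if isinstance(c, EvokedComponentSpec) else EvokedComponentSpec(**c)
            for c in self.components
        ]
        lats = [c.peak_latency for c in self.components]
        if lats != sorted(lats):
            raise ValidationError("evoked component latencies must be increasing")


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic session."""

    duration: float = 600.0
    base_rate: dict = field(default_factory=lambda: {"LC": 12.0, "TCC": 4.0})
    rhythms: dict = field(default_factory=dict)  # region -> list[RhythmSpec]
    coupling_lag: float = NAIVE_COUPLING_LAG  # s; positive = LC leads TCC
    shared_fraction: float = 0.8
    evoked: dict = field(default_factory=dict)  # region -> EvokedSpec
    tcc_phase_advance: float = 0.0  # radians, applied to one TCC rhythm
    tcc_advance_rhythm: str = "slow"
    lfp_noise_sd: float = 0.5
    fs_lfp: float = 1000.0
    fs_rate: float = 50.0
    n_lc_subtrains: int = 4
    train_starts: list = field(default_factory=list)  # electrical train onsets (s)
    n_stim_per_train: int = 50
    protocol: tuple = PROTOCOL_MENINGEAL  # (pulse_width, isi)
    condition: str = "naive"
    seed: int = 0

    def __post_init__(self):
        for region, rl in self.rhythms.items():
            self.rhythms[region] = [
                r if isinstance(r, RhythmSpec) else RhythmSpec(**r) for r in rl
            ]
        for region, ev in self.evoked.items():
            if not isinstance(ev, EvokedSpec):
                self.evoked[region] = EvokedSpec(**ev)
        if any(v < 0 for v in self.base_rate.values()):
            raise ValidationError("base rates must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValidationError("shared_fraction must lie in [0, 1]")
        if self.fs_lfp < 2 * DELTA_BAND[1]:
            raise ValidationError("fs_lfp must exceed twice the delta upper edge")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protocol"] = list(d["protocol"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = copy.deepcopy(d)
        d["protocol"] = tuple(d["protocol"])
        d["rhythms"] = {
            reg: [RhythmSpec(**r) for r in rl] for reg, rl in d.get("rhythms", {}).items()
        }
        d["evoked"] = {reg: EvokedSpec(**e) for reg, e in d.get("evoked", {}).items()}
        return cls(**d)


def _default_rhythms(slow_period, intermediate_period, lc_delta_depth):
    """Shared rhythm sets; depths are generator defaults (the recordings
    the analysis targets do not constrain modulation depth)."""
    common = lambda: [  # noqa: E731
        RhythmSpec(period=slow_period, depth=0.5, phase0=0.0, name="slow"),
        RhythmSpec(period=intermediate_period, depth=0.35, phase0=0.0, name="intermediate"),
    ]
    lc = common() + [RhythmSpec(period=1.25, depth=lc_delta_depth, phase0=0.0, name="delta")]
    tcc = common() + [RhythmSpec(period=1.25, depth=0.25, phase0=0.0, name="delta")]
    return {"LC": lc, "TCC": tcc}


def _default_evoked(lc_gain_scale=1.0, lc_late_scale=1.0):
    lc = EvokedSpec(
        components=[
            EvokedComponentSpec(LC_EARLY_LATENCY, 0.010, 8.0 * lc_gain_scale),
            EvokedComponentSpec(LC_LATE_LATENCY, 0.010, 5.0 * lc_gain_scale * lc_late_scale),
        ]
    )
    tcc = EvokedSpec(
        components=[
            EvokedComponentSpec(0.012, 0.004, 2.0),  # A-fiber response, < 30 ms
            EvokedComponentSpec(0.080, 0.020, 1.5),  # C-fiber response, 30-200 ms
        ]
    )
    return {"LC": lc, "TCC": tcc}


def preset(condition: str, seed: int = 0, duration: float = 600.0) -> GeneratorConfig:
    """Condition presets encoding the study conditions.

    * ``naive`` — slow/intermediate periods 400.4 s / 21.3 s, LC->TCC lag
      10.1 ms, LC evoked latencies 62.8 / 129.6 ms.
    * ``sensitized`` — TCC baseline raised 3x, periods 675.0 s / 20.5 s,
      positive TCC phase advance on the slow rhythm, LC late-component
      gain scaled by 0.3.
    * ``propranolol`` — LC delta-rhythm depth and LC evoked gains scaled
      down (0.3 / 0.4), otherwise naive.
    """
    if condition == "naive":
        cfg = GeneratorConfig(
            duration=duration,
            rhythms=_default_rhythms(NAIVE_SLOW_PERIOD, NAIVE_INTERMEDIATE_PERIOD, 0.25),
            evoked=_default_evoked(),
            condition="naive",
            seed=seed,
        )
    elif condition == "sensitized":
        cfg = GeneratorConfig(
            duration=duration,
            base_rate={"LC": 12.0, "TCC": 12.0},
            rhythms=_default_rhythms(
                SENSITIZED_SLOW_PERIOD, SENSITIZED_INTERMEDIATE_PERIOD, 0.25
            ),
            evoked=_default_evoked(lc_late_scale=0.3),
            tcc_phase_advance=math.pi / 8,
            tcc_advance_rhythm="slow",
            condition="sensitized",
            seed=seed,
        )
    elif condition == "propranolol":
        cfg = GeneratorConfig(
            duration=duration,
            rhythms=_default_rhythms(NAIVE_SLOW_PERIOD, NAIVE_INTERMEDIATE_PERIOD, 0.075),
            evoked=_default_evoked(lc_gain_scale=0.4),
            condition="propranolol",
            seed=seed,
        )
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return cfg


def _stable_key(x) -> int:
    return zlib.crc32(repr(x).encode())


def _rng_for(config_or_seed, *stream) -> np.random.Generator:
    seed = (
        config_or_seed if isinstance(config_or_seed, (int, np.integer))
        else config_or_seed.seed
    )
    return np.random.default_rng([int(seed) % (2**31), *map(_stable_key, stream)])


def rate_process(config: GeneratorConfig, region: str) -> UniformSignal:
    """Instantaneous firing rate (Hz) of *region*.

    rate(t) = base * prod_r [1 + depth_r * m_r(t)] clipped at 0, where each
    rhythm's modulation m_r mixes a shared and a region-private cosine by
    ``shared_fraction``; the TCC copy of every shared cosine is delayed by
    ``coupling_lag`` and, for the designated rhythm, phase-shifted by
    ``tcc_phase_advance``.
    """
    region = canonical_region(region)
    t = np.arange(int(round(config.duration * config.fs_rate))) / config.fs_rate
    base = config.base_rate.get(region, 0.0)
    rate = np.full_like(t, float(base))
    rng = _rng_for(config, "private_phase", region)
    for r in config.rhythms.get(region, []):
        omega = 2 * np.pi / r.period
        tt = t - config.coupling_lag if region == "TCC" else t
        phase = omega * tt + r.phase0
        if region == "TCC" and r.name == config.tcc_advance_rhythm:
            phase = phase - config.tcc_phase_advance
        shared = np.cos(phase)
        sf = config.shared_fraction
        if sf < 1.0:
            # private variability is detuned from the shared rhythm so it
            # decorrelates over the session instead of acting as a fixed
            # per-session phase offset
            detune = rng.uniform(0.05, 0.15) * rng.choice((-1.0, 1.0))
            private = np.cos(omega * (1.0 + detune) * t + rng.uniform(0, 2 * np.pi))
            m = sf * shared + (1.0 - sf) * private
        else:
            m = shared
        rate *= 1.0 + r.depth * m
    np.clip(rate, 0.0, None, out=rate)
    return UniformSignal(rate, config.fs_rate, 0.0, "rate")


def sample_spikes(rate: UniformSignal, seed: int, region: str = "LC",
                  unit_kind: str = "SU", id: str = "") -> SpikeTrain:
    """Inhomogeneous-Poisson spike train via thinning against the rate max."""
    if rate.kind != "rate":
        raise ValidationError("sample_spikes expects a rate-kind signal")
    values = rate.values
    if np.any(values < 0):
        raise ValidationError("rate must be non-negative")
    rmax = float(values.max())
    duration = rate.duration
    times = np.empty(0)
    if rmax > 0:
        rng = np.random.default_rng(seed)
        n = rng.poisson(rmax * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n))
        lam = np.interp(cand, rate.times(), values)
        keep = rng.uniform(0.0, rmax, size=n) < lam
        times = cand[keep]
        times = times[np.insert(np.diff(times) > 0, 0, True)]  # drop exact ties
    return SpikeTrain(rate.t0 + times, region, unit_kind, id)


def add_evoked(train: SpikeTrain, events: EventSeries, spec: EvokedSpec,
               seed: int) -> SpikeTrain:
    """Superimpose stimulus-locked extra spikes on *train*.

    Each component contributes, per stimulus, ``Poisson(gain)`` extra
    spikes at Gaussian latencies centered on ``peak_latency`` (sd =
    width * FWHM_TO_SD) truncated to ``[0, isi)``; original spikes are
    retained.
    """
    for c in spec.components:
        if c.peak_latency + 4 * c.width * FWHM_TO_SD >= events.isi:
            raise ValidationError(
                f"evoked component at {c.peak_latency}s extends beyond isi {events.isi}s"
            )
    rng = np.random.default_rng(seed)
    extra = []
    for c in spec.components:
        if c.gain == 0:
            continue
        counts = rng.poisson(c.gain, size=len(events))
        for onset, k in zip(events.onsets, counts):
            if k == 0:
                continue
            lat = rng.normal(c.peak_latency, c.width * FWHM_TO_SD, size=k)
            lat = lat[(lat >= 0) & (lat < events.isi)]
            extra.append(onset + lat)
    if not extra:
        return SpikeTrain(train.times.copy(), train.region, train.unit_kind, train.id)
    merged = np.sort(np.concatenate([train.times, *extra]))
    merged = merged[np.insert(np.diff(merged) > 0, 0, True)]
    return SpikeTrain(merged, train.region, train.unit_kind, train.id)


def _shared_delta_noise(config: GeneratorConfig, n: int, seed: int) -> np.ndarray:
    """Delta-band (0.3-2 Hz) narrowband noise common to both regions, unit sd.

    Built by brick-wall masking the spectrum of white noise (O(n log n);
    a time-domain FIR of the length the 0.3 Hz edge would need is far
    costlier on hours-long sessions)."""
    rng = _rng_for(seed, "lfp_shared")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs_lfp)
    spec[(freqs < DELTA_BAND[0]) | (freqs > DELTA_BAND[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def make_lfp(config: GeneratorConfig, region: str, seed: int = None) -> UniformSignal:
    """LFP = delta-band component of the shared drive + white noise.

    The delta-band narrowband noise is amplitude-modulated by the shared
    slower rhythms (slow/intermediate envelope), so delta LFP power waxes
    and wanes with the slow oscillation of population activity.  The TCC
    copy is the whole LC shared component delayed by ``coupling_lag``
    (linear interpolation; exact for a signal band-limited far below the
    sampling rate).
    """
    region = canonical_region(region)
    eff_seed = config.seed if seed is None else seed
    n = int(round(config.duration * config.fs_lfp))
    t = np.arange(n) / config.fs_lfp
    shared = _shared_delta_noise(config, n, eff_seed)
    env = np.ones(n)
    for r in config.rhythms.get("LC", []):
        if r.name == "delta":
            continue
        env *= 1.0 + r.depth * np.cos(2 * np.pi * t / r.period + r.phase0)
    np.clip(env, 0.0, None, out=env)
    shared = shared * env
    if region == "TCC" and config.coupling_lag != 0.0:
        shared = np.interp(t - config.coupling_lag, t, shared)
    rng = _rng_for(eff_seed, "lfp_noise", region)
    values = shared + config.lfp_noise_sd * rng.standard_normal(n)
    return UniformSignal(values, config.fs_lfp, 0.0, "lfp_raw")


def _default_train_starts(config: GeneratorConfig) -> list:
    """Electrical-train placement: if the session is long enough, three
    trains separated by >= 10 min gaps (so the synchronization index has
    its two inter-train windows); otherwise a single train at 30 s."""
    train_len = config.n_stim_per_train * config.protocol[1]
    need = 3 * train_len + 2 * 640.0 + 60.0
    if config.duration >= need:
        starts = [30.0]
        for _ in range(2):
            starts.append(starts[-1] + train_len + 640.0)
        return starts
    if config.duration >= train_len + 60.0:
        return [30.0]
    return []


def generate_session(config: GeneratorConfig) -> Session:
    """Compose rates, spikes, evoked responses, events and LFPs into a
    Session.  Deterministic: identical config (including seed) gives a
    bit-identical session."""
    starts = config.train_starts or _default_train_starts(config)
    pulse_width, isi = config.protocol
    events = [
        EventSeries(
            onsets=s + np.arange(config.n_stim_per_train) * isi,
            pulse_width=pulse_width,
            isi=isi,
            label="meningeal" if config.protocol == PROTOCOL_MENINGEAL else "cutaneous",
        )
        for s in starts
    ]

    trains = []
    # LC multi-unit record: union of independently thinned sub-trains.
    lc_rate = rate_process(config, "LC")
    sub_rate = UniformSignal(
        lc_rate.values / config.n_lc_subtrains, lc_rate.fs, lc_rate.t0, "rate"
    )
    sub_times = []
    for k in range(config.n_lc_subtrains):
        st = sample_spikes(sub_rate, _rng_for(config, "lc_sub", k).integers(2**31), "LC")
        sub_times.append(st.times)
    merged = np.sort(np.concatenate(sub_times)) if sub_times else np.empty(0)
    if merged.size:
        merged = merged[np.insert(np.diff(merged) > 0, 0, True)]
    lc_mua = SpikeTrain(merged, "LC", "MUA", "LC_mua")
    for ev in events:
        lc_mua = add_evoked(
            lc_mua, ev, config.evoked.get("LC", EvokedSpec()),
            _rng_for(config, "lc_ev", int(ev.onsets[0] * 1e3)).integers(2**31),
        )
    trains.append(lc_mua)

    tcc_rate = rate_process(config, "TCC")
    tcc = sample_spikes(
        tcc_rate, _rng_for(config, "tcc_su").integers(2**31), "TCC", "SU", "TCC_su"
    )
    for ev in events:
        tcc = add_evoked(
            tcc, ev, config.evoked.get("TCC", EvokedSpec()),
            _rng_for(config, "tcc_ev", int(ev.onsets[0] * 1e3)).integers(2**31),
        )
    trains.append(tcc)

    lfp = {r: make_lfp(config, r) for r in ("LC", "TCC")}
    return Session(
        duration=config.duration,
        spike_trains=trains,
        events=events,
        lfp=lfp,
        condition=config.condition,
        ground_truth=config.to_dict(),
    )
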