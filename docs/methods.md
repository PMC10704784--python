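# Methods

This note records the generative model behind `lctcc.simulate`, the
estimator conventions in the analysis modules, and the rationale for the
numerical defaults. Problem sizes quoted here (session durations, sampling
rates) are this package's own test choices.

## Generative model

### Rates and spikes

Each region's instantaneous firing rate is a multiplicatively modulated
baseline:

    rate(t) = base * Π_r [ 1 + depth_r · m_r(t) ]   (clipped at 0)

with one factor per rhythm *r* (slow, intermediate, delta). Each rhythm's
modulation mixes a **shared** cosine and a **region-private** cosine:

    m_r(t) = sf · cos(ω_r t + φ_r)  +  (1 − sf) · cos(ω_r (1+δ) t + ψ)

* `sf` is `shared_fraction` (default 0.8). The TCC copy of every shared
  cosine is evaluated at `t − coupling_lag`, making the LC lead by a directed
  delay (naive preset: 10.1 ms); for one designated rhythm the TCC phase is
  additionally advanced by `tcc_phase_advance`, which is what the precession
  estimator must recover.
* The private cosine is **detuned** by δ ∈ ±[5%, 15%] (seeded per
  region/rhythm). An un-detuned private cosine at the shared frequency acts
  as a fixed per-session phase offset and biases the recovered precession no
  matter how long the session; a detuned one decorrelates over the session
  and behaves as genuine private variability.

Spikes are drawn from the rate by inhomogeneous-Poisson **thinning**.
The LC multi-unit record is the union of `n_lc_subtrains` (4) independently
thinned trains from the per-subtrain rate, mirroring multi-unit extraction;
the TCC record is a single unit. Correctness is tested with a Poisson count
oracle and the time-rescaling theorem (rescaled inter-spike intervals are
Exp(1)).

### Evoked components

Each stimulus adds `Poisson(gain)` extra spikes per component at Gaussian
latencies centred on `peak_latency`, truncated to `[0, isi)`.

* `gain` is the expected number of extra spikes per stimulus (the integral
  of the rate bump) — the quantity PSTH recovery actually constrains.
* `width` is the bump's **FWHM**, the width one reads off a PSTH. (With
  sd-semantics, defaults wide enough to look physiological make the LC
  early/late bumps at 62.8 and 129.6 ms overlap and fuse.)

### LFP

The LFP is delta-band (0.3–2 Hz) narrowband noise shared between regions,
amplitude-modulated by the envelope of the slower rhythms, plus white
sensor noise:

* The narrowband noise is built by brick-wall masking the FFT of white
  noise — O(n log n), where a time-domain FIR sharp at 0.3 Hz would be
  prohibitively long on hours of 1 kHz signal.
* The envelope modulation (product of the slow/intermediate cosine factors,
  clipped at 0) makes delta LFP power wax and wane with the infra-slow
  rhythm of population activity; without it the delta-power timecourse is
  statistically flat and the sliding R² against the slow rate is
  meaningless.
* The TCC copy is the whole shared component delayed by `coupling_lag` via
  linear interpolation — exact for a signal band-limited far below the
  sampling rate.

### Presets

* `naive` — slow/intermediate periods 400.4 s / 21.3 s, coupling lag
  10.1 ms, LC evoked latencies 62.8 / 129.6 ms, TCC A/C components at
  12 / 80 ms.
* `sensitized` — TCC baseline raised 3×, periods 675.0 s / 20.5 s, a
  positive TCC phase advance (π/8 on the slow rhythm), LC late-component
  gain reduced.
* `propranolol` — LC delta-rhythm depth and LC evoked gains scaled down
  (0.3 / 0.4), otherwise naive.

The generator's delta rhythm period is **1.25 s**, not 1.0 s: a 1.0 s period
divides the 2.0 s meningeal inter-stimulus interval exactly, phase-locking
stimuli to the delta rhythm and building a coherent PSTH bump that can
bridge the two LC evoked components. 1.25 s is non-commensurate with both
stimulation protocols (0.8 ms pulses @ 1.5 s; 5 ms pulses @ 2 s).

All randomness derives from `numpy.random.default_rng` keyed by the config
seed plus CRC32-hashed stream labels, so sessions are bit-reproducible
across processes (Python's built-in `hash` is process-randomized and is
deliberately not used).

## Estimators

### PSTH and evoked components

`build_psth` bins spike offsets in `[0, window)` after each stimulus
(half-open bins). The **evoked-bin criterion** flags a bin when its rate is
strictly greater than the mean rate of the bins lying fully in the last
500 ms of the window. Component extraction then:

1. merges runs of flagged bins separated by ≤ `merge_gap` (default 2)
   unflagged bins;
2. keeps a run only if its spike count is improbable under a Poisson
   baseline at the tail rate (one-sided p < 1e-4) — with 1 ms bins and a
   tonic baseline the strict criterion flags ~45% of bins by chance, so an
   unscreened run list is mostly noise;
3. locates each peak on a Gaussian-smoothed (sd 3 bins) copy of the rates
   so single-bin count noise does not set the time-to-peak;
4. splits TCC runs straddling 30 ms at the A/C boundary, and splits LC runs
   whose smoothed profile has two well-separated peaks at the intervening
   trough (early and late components can share a run when the baseline
   between them stays slightly elevated);
5. classifies TCC components by peak latency ([0, 30) ms → A,
   [30, 200) ms → C) and LC components by temporal order (early, late).

Magnitude = (mean in-run rate − tail mean) / pre-train baseline rate (30 s
before the first stimulus); undefined (None) when the baseline is silent.
The LC/TCC coupling ratio is 100 · LC-early magnitude / total TCC A-spikes.

### Rhythms

`mean_frequency` evaluates, at each spike, the spike count in a centred
window divided by the window width, resamples to a uniform grid, and zeroes
grid points with no spike within half a window. Defaults per band
(window, output rate): slow (100 s, 2 Hz), intermediate (10 s, 2 Hz), delta
(0.5 s, 50 Hz).

`estimate_period` band-passes the rate with a zero-phase FIR (numtaps
≈ 4·fs/low-edge, capped at half the signal) and takes the lag of the
dominant positive-lag autocorrelation peak within [1/high, 1/low]. It is
invariant to scaling/offsets and raises `PeriodEstimationError` when the
normalized peak is below 0.1 (no confident rhythm) — callers record this
as a reason instead of a number. The precondition is ≥ 4 cycles of the
band's low edge.

`instantaneous_phase` is the Hilbert phase of the band-passed rate (phase 0
at the oscillation peak); one filter length at each end is marked
edge-contaminated and excluded from phase histograms. Histograms use 75 or
150 bins per cycle, are z-scored, and the preferred phase is the circular
mean of spike phases. **Precession** = wrap(TCC preferred − LC preferred)
into (−π, π], both histograms built against the LC reference phase; with
this sign convention the generator's `tcc_phase_advance` is recovered as
+advance.

### Synchronization

`delta_power_ratio` is the 0.3–2 Hz fraction of total above-DC periodogram
power of a rate signal (scale-invariant; needs ≥ 10 delta cycles).
`sync_index` averages it over two 10-minute windows centred in the first
two ≥ 10-minute gaps between stimulation trains.

The LFP chain: zero-phase decimation to 50 Hz → spectrogram (Hamming 1024,
overlap 1014, FFT length 8096 — kept literally as specified, not rounded to
a power of two; 10-sample hop → 5 frames/s) → per-frame trapezoidal
integral of log10 PSD over 0.3–2 Hz → Savitzky–Golay smoothing (order 3,
51 samples) of that timecourse and of the slow MUA rate on a common grid →
squared Pearson correlation per 400-s window, 10-s hop; `r2max` is the
maximum over windows.

`crosscorrelogram_lag` takes the peak of the LFP–LFP cross-correlogram in
±200 ms. Because delta-band-limited signals carry no correlogram structure
above the band, the lag axis is low-pass filtered (zero-phase FIR, 4 Hz
cutoff) and the peak is refined by parabolic interpolation; this reduces
the estimator sd from ~1.4 ms to ~0.15 ms on 600-s naive sessions while
staying antisymmetric under swapping inputs. Positive lag = LC leads.

### Statistics

`lilliefors` computes the KS distance between the sample ECDF and a normal
with estimated mean/sd, with p-values from a seeded Monte-Carlo null
(10 000 replicates per sample size, cached; p = (count+1)/(N+1)).
`compare_groups` gates on Lilliefors normality (of the paired differences,
or of each sample) at α = 0.05: Student's t when normal, otherwise Wilcoxon
signed-rank / Mann–Whitney U. Zero-variance samples force the nonparametric
branch and are flagged `degenerate`. Calibration: type-I error ≈ 4.6% at
n = 30 under a Gaussian null (acceptance bound ≤ 7%).

## Limitations

* The generator's modulation depths, baseline rates and evoked gains are
  plausible defaults, not fitted to recordings; only periods, lags,
  latencies and phase offsets are set to observed values.
* Rate rhythms are deterministic cosines (plus detuned private cosines),
  not stochastic oscillators; period recovery tolerances reflect estimator
  bias/variance, not drift.
* The LFP model contains only the shared delta component and white noise —
  no 1/f background, line noise or spikes-in-LFP leakage.
* Slow-band period estimation needs multi-hour sessions (≥ 4 cycles of the
  1/1200 Hz low edge); shorter sessions report the reason instead.
* No plotting is included; reports serialize to JSON/Markdown and
  spectrograms are plain arrays.
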