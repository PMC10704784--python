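"""Spontaneous-activity rhythms: mean frequency, oscillation periods,
spike-phase histograms, preferred phase and precession.

The mean-frequency estimator evaluates, at each spike, the spike count in
a centred window divided by the window width, then resamples that
irregular series onto a uniform grid.  Oscillation periods come from the
autocorrelation of the band-passed rate; phase from a zero-phase FIR
band-pass followed by the Hilbert transform (phase 0 at the oscillation
peak, cosine convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import SpikeTrain, UniformSignal, ValidationError, wrap_phase

__all__ = [
    "BandSpec",
    "BANDS",
    "PhaseHistogram",
    "mean_frequency",
    "estimate_period",
    "PeriodEstimationError",
    "instantaneous_phase",
    "phase_histogram",
    "precession",
]


@dataclass(frozen=True)
class BandSpec:
    low: float   # Hz
    high: float  # Hz
    name: str

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValidationError("need 0 < low < high")


# Slow and intermediate edges bracket the observed periods (~400-675 s and
# ~20-21 s) with margin; delta is the standard 0.3-2 Hz band.
BANDS = {
    "slow": BandSpec(1 / 1200, 1 / 120, "slow"),
    "intermediate": BandSpec(1 / 40, 1 / 12, "intermediate"),
    "delta": BandSpec(0.3, 2.0, "delta"),
}

# analysis defaults per band: (mean-frequency window s, output rate Hz)
MEAN_FREQ_DEFAULTS = {"slow": (100.0, 2.0), "intermediate": (10.0, 2.0), "delta": (0.5, 50.0)}


class PeriodEstimationError(RuntimeError):
    """No sufficiently prominent autocorrelation peak in the queried band."""


def mean_frequency(train: SpikeTrain, width: float, fs_out: float,
                   duration: float = None) -> UniformSignal:
    """Instantaneous mean firing rate resampled to a uniform grid.

    Rate at each spike = (spike count in the centred window of length
    *width*) / *width*; linearly interpolated between spikes and set to
    zero at grid points with no spike within width/2."""
    if not width > 0 or not fs_out > 0:
        raise ValidationError("width and fs_out must be positive")
    if duration is None:
        duration = float(train.times[-1]) if len(train) else 1.0
    n = max(int(round(duration * fs_out)), 2)
    grid = np.arange(n) / fs_out
    if len(train) == 0:
        return UniformSignal(np.zeros(n), fs_out, 0.0, "rate")
    s = train.times
    counts = np.searchsorted(s, s + width / 2, side="left") - np.searchsorted(
        s, s - width / 2, side="left"
    )
    vals = counts / width
    out = np.interp(grid, s, vals)
    # zero wherever no spike lies within width/2 of the grid point
    nearest = np.searchsorted(s, grid)
    left = np.abs(grid - s[np.clip(nearest - 1, 0, s.size - 1)])
    right = np.abs(s[np.clip(nearest, 0, s.size - 1)] - grid)
    out[np.minimum(left, right) > width / 2] = 0.0
    return UniformSignal(out, fs_out, 0.0, "rate")


def _fir_bandpass(x: np.ndarray, fs: float, band: BandSpec) -> tuple:
    """Zero-phase FIR band-pass; returns (filtered, numtaps)."""
    if band.high >= fs / 2:
        raise ValidationError(f"band edge {band.high} Hz at or above Nyquist {fs / 2} Hz")
    n = x.size
    # transition width scales as fs/numtaps: the low edge needs long filters
    numtaps = int(round(4 * fs / band.low)) | 1
    numtaps = min(numtaps, (n // 2) | 1)
    if numtaps < 5:
        raise ValidationError("signal too short to filter in this band")
    taps = sps.firwin(numtaps, [band.low, band.high], fs=fs, pass_zero=False)
    return sps.filtfilt(taps, 1.0, x, padlen=min(3 * numtaps, n - 1)), numtaps


def estimate_period(rate: UniformSignal, band, min_prominence: float = 0.1) -> float:
    """Oscillation period: lag of the dominant positive-lag autocorrelation
    peak of the band-passed signal, restricted to [1/high, 1/low] s.

    Invariant to amplitude scaling and additive constants.  Raises
    :class:`PeriodEstimationError` when no candidate peak reaches
    *min_prominence* (in units of the zero-lag autocorrelation) — the
    band holds no detectable rhythm."""
    if isinstance(band, str):
        band = BANDS[band]
    need = 4.0 / band.low
    if rate.duration < need:
        raise ValidationError(
            f"duration {rate.duration:.0f}s < required {need:.0f}s (4 cycles at {band.low} Hz)"
        )
    x = rate.values - rate.values.mean()
    y, _ = _fir_bandpass(x, rate.fs, band)
    n = y.size
    ac = sps.fftconvolve(y, y[::-1], mode="full")[n - 1:]
    ac /= ac[0] if ac[0] > 0 else 1.0
    lag_lo = max(int(np.floor(rate.fs / band.high)), 1)
    lag_hi = min(int(np.ceil(rate.fs / band.low)), n - 1)
    if lag_hi <= lag_lo:
        raise ValidationError("band not resolvable at this sampling rate")
    seg = ac[lag_lo : lag_hi + 1]
    peaks, props = sps.find_peaks(seg, prominence=0.0)
    if peaks.size == 0:
        raise PeriodEstimationError(f"no autocorrelation peak in band {band.name!r}")
    best = peaks[np.argmax(seg[peaks])]
    if seg[best] < min_prominence:
        raise PeriodEstimationError(
            f"peak autocorrelation {seg[best]:.3f} below {min_prominence} in "
            f"band {band.name!r}: low confidence"
        )
    return float((lag_lo + best) / rate.fs)


def instantaneous_phase(rate: UniformSignal, band) -> UniformSignal:
    """Band-pass (zero-phase FIR) then Hilbert phase, wrapped to (-pi, pi].

    Phase 0 falls at the oscillation peak.  The first and last
    filter-length samples are edge-contaminated; their span is recorded in
    ``edge_margin`` and excluded by :func:`phase_histogram`."""
    if isinstance(band, str):
        band = BANDS[band]
    if rate.duration < 3.0 / band.low:
        raise ValidationError(f"need at least 3 cycles of {1 / band.low:.0f}s")
    y, numtaps = _fir_bandpass(rate.values - rate.values.mean(), rate.fs, band)
    phi = np.angle(sps.hilbert(y))
    return UniformSignal(
        wrap_phase(phi), rate.fs, rate.t0, "phase", edge_margin=numtaps / rate.fs
    )


@dataclass
class PhaseHistogram:
    """Spike counts per phase bin of one oscillation cycle."""

    n_bins: int
    counts: np.ndarray
    z: np.ndarray           # z-scored counts (mean 0, sd 1) when non-constant
    preferred: float        # circular mean angle of spike phases, radians
    n_excluded: int = 0     # spikes outside phase coverage / in edge margins

    def bin_centers(self) -> np.ndarray:
        w = 2 * np.pi / self.n_bins
        return -np.pi + w * (np.arange(self.n_bins) + 0.5)


def phase_histogram(train: SpikeTrain, phase: UniformSignal, n_bins: int = 150) -> PhaseHistogram:
    """Allocate each spike to the phase bin it occurred in (75 or 150 bins
    per cycle) and z-score the histogram to keep only temporal dynamics."""
    if n_bins not in (75, 150):
        raise ValidationError("n_bins must be 75 or 150")
    if phase.kind != "phase":
        raise ValidationError("phase_histogram expects a phase-kind signal")
    t_lo = phase.t0 + phase.edge_margin
    t_hi = phase.t0 + phase.duration - phase.edge_margin
    inside = (train.times >= t_lo) & (train.times <= t_hi)
    n_excluded = int(np.count_nonzero(~inside))
    times = train.times[inside]
    idx = np.clip(np.round((times - phase.t0) * phase.fs).astype(int), 0, phase.values.size - 1)
    phis = phase.values[idx]
    w = 2 * np.pi / n_bins
    bins = np.minimum(((phis + np.pi) / w).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    sd = counts.std()
    z = (counts - counts.mean()) / sd if sd > 0 else np.zeros(n_bins)
    preferred = float(np.angle(np.exp(1j * phis).sum())) if phis.size else 0.0
    return PhaseHistogram(n_bins, counts, z, wrap_phase(preferred), n_excluded)


def precession(tcc: PhaseHistogram, lc: PhaseHistogram) -> float:
    """Circular difference of preferred phases, TCC minus LC, in (-pi, pi].

    Both histograms must be built against the same reference phase signal
    (same bin count enforced as a proxy)."""
    if tcc.n_bins != lc.n_bins:
        raise ValidationError("histograms built with different n_bins")
    return wrap_phase(tcc.preferred - lc.preferred)
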