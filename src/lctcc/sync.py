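"""Delta-band synchronization measures on MUA rates and LFPs.

* ``delta_power_ratio`` / ``sync_index`` — fraction of the mean-frequency
  signal's power in the 0.3-2 Hz delta band, averaged over two 10-minute
  windows between electrical-stimulation trains.
* ``decimate_lfp`` / ``spectrogram`` / ``delta_band_timecourse`` — LFP
  decimated to 50 Hz, short-time Fourier transform (Hamming window of
  1024 samples, overlap 1014, FFT length 8096), log-PSD integrated over
  0.3-2 Hz as a time-varying delta-activity trace.
* ``sliding_r2`` — squared Pearson correlation between that trace and the
  slow component of the MUA mean frequency, on 400-s sliding windows
  after Savitzky-Golay smoothing (order 3, 51 samples); the maximum over
  windows is the per-session R^2 max.
* ``crosscorrelogram_lag`` — lag of the cross-correlogram peak between
  the two regions' LFPs; positive means the LC leads the TCC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import UniformSignal, ValidationError

__all__ = [
    "Spectrogram",
    "SyncIndex",
    "delta_power_ratio",
    "sync_index",
    "decimate_lfp",
    "spectrogram",
    "delta_band_timecourse",
    "sliding_r2",
    "crosscorrelogram_lag",
]

DELTA_BAND = (0.3, 2.0)
LFP_FS = 50.0
STFT_WINDOW = 1024
STFT_OVERLAP = 1014
STFT_NFFT = 8096  # as specified by the analysis protocol (not a power of two)
SYNC_WINDOW = 600.0       # s: each inter-train window for the sync index
MIN_DELTA_WINDOW = 10 / DELTA_BAND[0]  # s: >= 10 cycles at the low edge
R2_WINDOW = 400.0         # s
R2_HOP = 10.0             # s
SAVGOL_ORDER = 3
SAVGOL_FRAME = 51


@dataclass
class Spectrogram:
    times: np.ndarray     # s, frame centers
    freqs: np.ndarray     # Hz
    log_psd: np.ndarray   # (n_freqs, n_times)
    frame_fs: float       # frames per second


@dataclass
class SyncIndex:
    value: float                 # mean delta/total power ratio over windows
    windows: list                # [(start, end), ...] in s
    degenerate: bool = False     # True when total AC power was zero


def delta_power_ratio(rate: UniformSignal, window: tuple = None) -> float:
    """Power in 0.3-2 Hz over total power above DC, from a periodogram of
    the mean-frequency signal.  Invariant under amplitude scaling."""
    if rate.fs < 4.0:
        raise ValidationError("delta_power_ratio needs fs >= 4 Hz")
    sig = rate if window is None else rate.slice(*window)
    if sig.duration < MIN_DELTA_WINDOW:
        raise ValidationError(
            f"window of {sig.duration:.1f}s holds fewer than 10 delta cycles "
            f"(need >= {MIN_DELTA_WINDOW:.0f}s)"
        )
    freqs, psd = sps.periodogram(sig.values, fs=sig.fs, detrend="constant")
    ac = freqs > 0
    total = float(np.trapezoid(psd[ac], freqs[ac]))
    if total <= 0:
        return 0.0
    band = ac & (freqs >= DELTA_BAND[0]) & (freqs <= DELTA_BAND[1])
    return float(np.trapezoid(psd[band], freqs[band]) / total)


def _inter_train_gaps(stim_trains: list, t_end: float) -> list:
    """(start, end) spans strictly between consecutive stimulation trains."""
    spans = sorted((ev.onsets[0], ev.onsets[-1] + ev.isi) for ev in stim_trains if len(ev))
    return [
        (spans[k][1], spans[k + 1][0])
        for k in range(len(spans) - 1)
        if spans[k + 1][0] > spans[k][1]
    ]


def sync_index(rate: UniformSignal, stim_trains: list) -> SyncIndex:
    """Mean delta/total power ratio over two 10-min windows lying strictly
    between trains of electrical stimulations."""
    gaps = _inter_train_gaps(stim_trains, rate.t0 + rate.duration)
    usable = [g for g in gaps if g[1] - g[0] >= SYNC_WINDOW]
    if len(usable) < 2:
        raise ValidationError(
            f"need two inter-train gaps of >= {SYNC_WINDOW:.0f}s; available gaps: "
            + (", ".join(f"{b - a:.0f}s" for a, b in gaps) or "none")
        )
    windows = []
    for a, b in usable[:2]:
        mid = (a + b) / 2
        windows.append((mid - SYNC_WINDOW / 2, mid + SYNC_WINDOW / 2))
    ratios = [delta_power_ratio(rate, w) for w in windows]
    degenerate = all(r == 0.0 for r in ratios)
    return SyncIndex(float(np.mean(ratios)), windows, degenerate)


def decimate_lfp(lfp: UniformSignal) -> UniformSignal:
    """Low-pass filter (zero-phase, cutoff <= 25 Hz) and downsample the raw
    LFP to 50 Hz."""
    if lfp.fs < 2 * LFP_FS:
        raise ValidationError(f"input fs {lfp.fs} Hz too low to decimate to {LFP_FS} Hz")
    if lfp.fs == LFP_FS:
        return UniformSignal(lfp.values.copy(), LFP_FS, lfp.t0, "lfp_decimated")
    ratio = lfp.fs / LFP_FS
    if abs(ratio - round(ratio)) < 1e-9:
        x = lfp.values
        q = int(round(ratio))
        # stage the decimation; zero-phase FIR keeps group delay at zero
        for stage_q in _stage_factors(q):
            x = sps.decimate(x, stage_q, ftype="fir", zero_phase=True)
    else:  # rational resampling for awkward input rates
        from fractions import Fraction

        frac = Fraction(LFP_FS / lfp.fs).limit_denominator(10000)
        x = sps.resample_poly(lfp.values, frac.numerator, frac.denominator)
    return UniformSignal(x, LFP_FS, lfp.t0, "lfp_decimated")


def _stage_factors(q: int) -> list:
    """Split a decimation factor into stages of at most 10."""
    stages = []
    while q > 10:
        for f in (10, 8, 5, 4, 2):
            if q % f == 0:
                stages.append(f)
                q //= f
                break
        else:
            stages.append(q)
            q = 1
    if q > 1:
        stages.append(q)
    return stages


def spectrogram(lfp50: UniformSignal) -> Spectrogram:
    """Short-time Fourier transform of the 50 Hz LFP with the protocol's
    parameters: Hamming 1024, overlap 1014 (hop 10 samples), FFT length
    8096; log10 of the PSD is stored."""
    if abs(lfp50.fs - LFP_FS) > 1e-9:
        raise ValidationError("spectrogram expects a 50 Hz decimated LFP")
    if lfp50.values.size < STFT_WINDOW:
        raise ValidationError(f"need >= {STFT_WINDOW} samples")
    freqs, times, psd = sps.spectrogram(
        lfp50.values,
        fs=lfp50.fs,
        window=sps.get_window("hamming", STFT_WINDOW),
        nperseg=STFT_WINDOW,
        noverlap=STFT_OVERLAP,
        nfft=STFT_NFFT,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    hop = STFT_WINDOW - STFT_OVERLAP
    return Spectrogram(
        times=times + lfp50.t0,
        freqs=freqs,
        log_psd=np.log10(np.maximum(psd, 1e-300)),
        frame_fs=lfp50.fs / hop,
    )


def delta_band_timecourse(spec: Spectrogram) -> UniformSignal:
    """Per-frame trapezoidal integral of the log-PSD over 0.3-2 Hz: a
    time-varying index of low-frequency LFP activity."""
    band = (spec.freqs >= DELTA_BAND[0]) & (spec.freqs <= DELTA_BAND[1])
    vals = np.trapezoid(spec.log_psd[band, :], spec.freqs[band], axis=0)
    return UniformSignal(vals, spec.frame_fs, float(spec.times[0]), "band_power")


def _common_grid(a: UniformSignal, b: UniformSignal) -> tuple:
    """Resample both signals onto the coarser of the two rates over the
    overlapping span."""
    fs = min(a.fs, b.fs)
    t0 = max(a.t0, b.t0)
    t1 = min(a.t0 + a.duration, b.t0 + b.duration)
    if t1 <= t0:
        raise ValidationError("signals do not overlap in time")
    grid = t0 + np.arange(int((t1 - t0) * fs)) / fs
    va = np.interp(grid, a.times(), a.values)
    vb = np.interp(grid, b.times(), b.values)
    return grid, va, vb, fs


def sliding_r2(band_power: UniformSignal, slow_rate: UniformSignal) -> dict:
    """Squared Pearson correlation between the delta-power timecourse and
    the slow MUA mean frequency, per 400-s sliding window (10-s hop) after
    Savitzky-Golay smoothing (order 3, 51 samples).

    Returns ``{"r2_series": UniformSignal, "r2max": float}``.  Invariant
    to affine transforms of either input."""
    grid, va, vb, fs = _common_grid(band_power, slow_rate)
    if grid[-1] - grid[0] < R2_WINDOW:
        raise ValidationError(f"overlap {grid[-1] - grid[0]:.0f}s < {R2_WINDOW:.0f}s window")
    frame = min(SAVGOL_FRAME, (va.size - 1) | 1)
    va = sps.savgol_filter(va, frame, SAVGOL_ORDER)
    vb = sps.savgol_filter(vb, frame, SAVGOL_ORDER)
    wlen = int(round(R2_WINDOW * fs))
    hop = max(int(round(R2_HOP * fs)), 1)
    starts = np.arange(0, va.size - wlen + 1, hop)
    r2 = np.empty(starts.size)
    for k, s in enumerate(starts):
        xa, xb = va[s : s + wlen], vb[s : s + wlen]
        sa, sb = xa.std(), xb.std()
        if sa == 0 or sb == 0:
            r2[k] = 0.0
        else:
            r2[k] = float(np.corrcoef(xa, xb)[0, 1] ** 2)
    series = UniformSignal(
        r2 if r2.size >= 2 else np.r_[r2, r2], 1.0 / R2_HOP, float(grid[0] + R2_WINDOW / 2),
        "band_power",
    )
    return {"r2_series": series, "r2max": float(np.max(r2))}


def crosscorrelogram_lag(lfp_lc: UniformSignal, lfp_tcc: UniformSignal,
                         max_lag: float = 0.2, smooth_cutoff: float = 4.0) -> float:
    """Lag (s) of the normalized cross-correlogram peak between the two
    regions' LFPs within [-max_lag, +max_lag]; positive = LC leads TCC.

    The empirical correlogram of delta-band-limited signals carries no
    information above the band, so lag-axis content above *smooth_cutoff*
    (Hz; twice the delta upper edge by default) is removed with a
    zero-phase FIR before peak picking, and the peak is refined by
    parabolic interpolation.  Antisymmetric under swapping the inputs;
    pass ``smooth_cutoff=None`` for the raw discrete argmax."""
    if abs(lfp_lc.fs - lfp_tcc.fs) > 1e-9 or abs(lfp_lc.t0 - lfp_tcc.t0) > 1e-9:
        raise ValidationError("LFPs must share fs and t0")
    a = lfp_lc.values - lfp_lc.values.mean()
    b = lfp_tcc.values - lfp_tcc.values.mean()
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("constant signal: cross-correlogram lag undefined")
    fs = lfp_lc.fs
    m = int(round(max_lag * fs))
    cc = sps.fftconvolve(a, b[::-1], mode="full")
    lags = np.arange(-(b.size - 1), a.size)  # index of a minus index of b
    margin = 0
    if smooth_cutoff is not None and smooth_cutoff < fs / 2:
        ntaps = min(int(round(2 * fs / smooth_cutoff)) | 1, (cc.size // 4) | 1)
        if ntaps >= 5:
            margin = 3 * ntaps
            keep = (lags >= -m - margin) & (lags <= m + margin)
            cc, lags = cc[keep], lags[keep]
            taps = sps.firwin(ntaps, smooth_cutoff, fs=fs)
            cc = sps.filtfilt(taps, 1.0, cc, padlen=min(3 * ntaps, cc.size - 1))
    keep = (lags >= -m) & (lags <= m)
    cc, lags = cc[keep], lags[keep]
    k = int(np.argmax(cc))
    lag = float(lags[k])
    if 0 < k < cc.size - 1:  # parabolic sub-sample refinement
        y0, y1, y2 = cc[k - 1], cc[k], cc[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag += float(0.5 * (y0 - y2) / denom)
    # correlate(a, b) peaks at lag -D when b is a delayed by D samples,
    # so negate to report positive lag when the LC leads.
    return -lag / fs
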