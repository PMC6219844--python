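"""Spectral analysis: Morlet spectrograms, instantaneous frequency and
power tracks, clamped/unclamped ratios, and LED–LFP phase estimation.

The gamma oscillation is non-stationary, so frequency is tracked by a
single-tone estimate on successive overlapping windowed segments
(band-limited spectral peak with local quadratic interpolation on the
log magnitude) and power is read at the estimated tone frequency.
Clamp effects are summarised as the ratios F_clamped/F_unclamped and
P_clamped/P_unclamped, with the unclamped estimates taken from 1 s
flanks before and after the clamp window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .core import SimRun, TimeSeries

__all__ = [
    "Spectrogram",
    "SpectralSummary",
    "morlet_spectrogram",
    "instantaneous_freq_power",
    "clamp_ratios",
    "led_lfp_phase",
]


@dataclass
class Spectrogram:
    times: np.ndarray
    freqs: np.ndarray
    magnitude: np.ndarray  # (n_freqs, n_times), non-negative

    def __post_init__(self):
        if np.any(self.magnitude < 0):
            raise ValueError("spectrogram magnitudes must be non-negative")


@dataclass
class SpectralSummary:
    freq_track: TimeSeries
    power_track: TimeSeries
    f_clamped: float
    f_unclamped: float
    p_clamped: float
    p_unclamped: float
    meta: dict = field(default_factory=dict)

    @property
    def f_ratio(self) -> float:
        return self.f_clamped / self.f_unclamped

    @property
    def p_ratio(self) -> float:
        return self.p_clamped / self.p_unclamped


def morlet_spectrogram(ts: TimeSeries, f_lo: float = 20.0, f_hi: float = 120.0,
                       n_freqs: int = 100, wavelet_cycles: float = 7.0,
                       max_fs: float = 1000.0) -> Spectrogram:
    """Complex Morlet wavelet transform magnitude on a log-spaced grid.

    The signal is decimated to ``max_fs`` (if well above the analysis
    band) before the transform, which changes nothing below the band
    edge but keeps the coefficient matrix small.
    """
    if f_hi >= 0.5 * ts.fs:
        raise ValueError("f_hi must be below the Nyquist frequency")
    if f_lo <= 0 or f_lo >= f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    x, fs = ts.values, ts.fs
    q = int(fs // max_fs)
    if q > 1 and f_hi < 0.4 * fs / q:
        x = sps.resample_poly(x, 1, q)
        fs = fs / q
    dt = 1.0 / fs
    freqs = np.geomspace(f_lo, f_hi, n_freqs)
    # cmorB-C: exp(2*pi*1j*C*t) * exp(-t^2/B); match an n-cycle Morlet
    bw = 2.0 * (wavelet_cycles / (2 * math.pi)) ** 2
    wavelet = f"cmor{bw:.6f}-1.0"
    scales = 1.0 / (freqs * dt)
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=dt)
    # normalize out the sqrt(scale) amplitude factor so a pure tone's
    # response is centered on its own frequency, not tilted low
    mag = np.abs(coef) / np.sqrt(scales)[:, None]
    times = ts.t0 + np.arange(x.size) * dt
    return Spectrogram(times=times, freqs=freqs, magnitude=mag)


def _tone_estimate(seg: np.ndarray, fs: float, band: tuple[float, float],
                   pad_factor: int = 8) -> tuple[float, float]:
    """Single-tone frequency and power of a windowed segment.

    Returns (freq_hz, power) where power is A^2/2 for a tone of
    amplitude A, or (nan, nan) when no in-band energy stands above the
    numerical floor.
    """
    n = seg.size
    w = np.hanning(n)
    xw = (seg - seg.mean()) * w
    nfft = 1 << int(np.ceil(np.log2(max(n * pad_factor, 16))))
    spec = np.fft.rfft(xw, nfft)
    f = np.fft.rfftfreq(nfft, 1.0 / fs)
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel):
        return (math.nan, math.nan)
    mag = np.abs(spec[sel])
    k = int(np.argmax(mag))
    if mag[k] < 1e-9 * max(1.0, np.abs(xw).sum()):
        return (math.nan, math.nan)
    idx = np.nonzero(sel)[0]
    j = idx[k]
    # quadratic interpolation of log magnitude around the peak bin
    if 0 < j < f.size - 1 and spec[j - 1] != 0 and spec[j + 1] != 0:
        la, lb, lc = (math.log(abs(spec[j - 1])), math.log(abs(spec[j])),
                      math.log(abs(spec[j + 1])))
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        peak_log = lb - 0.25 * (la - lc) * delta
        f_hat = f[j] + delta * (f[1] - f[0])
        amp = 2.0 * math.exp(peak_log) / w.sum()
    else:
        f_hat = f[j]
        amp = 2.0 * mag[k] / w.sum()
    return (float(f_hat), 0.5 * amp * amp)


def instantaneous_freq_power(ts: TimeSeries, seg_len_ms: float = 200.0,
                             overlap_frac: float = 0.75,
                             band: tuple[float, float] = (20.0, 120.0),
                             ) -> tuple[TimeSeries, TimeSeries]:
    """Frequency and power tracks from overlapping single-tone estimates.

    Each segment of ``seg_len_ms`` is Hann-windowed and its dominant
    in-band tone located; tracks are sampled at the segment hop, time-
    stamped at segment centers.  Segments with no in-band energy above
    the floor yield NaN samples rather than raising.
    """
    if band[1] >= 0.5 * ts.fs:
        raise ValueError("band upper edge must be below Nyquist")
    nseg = int(round(seg_len_ms * 1e-3 * ts.fs))
    if nseg * band[0] / ts.fs < 4.0:
        raise ValueError("segment must span at least 4 cycles of the band low edge")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac in [0, 1)")
    hop = max(1, int(round(nseg * (1.0 - overlap_frac))))
    starts = np.arange(0, ts.n - nseg + 1, hop)
    fvals = np.empty(starts.size)
    pvals = np.empty(starts.size)
    for m, s in enumerate(starts):
        fvals[m], pvals[m] = _tone_estimate(ts.values[s:s + nseg], ts.fs, band)
    t0 = ts.t0 + (nseg / 2) * ts.dt
    dt_track = hop * ts.dt
    return (
        TimeSeries(fvals, dt_track, "Hz", t0),
        TimeSeries(pvals, dt_track, f"({ts.units})^2", t0),
    )


def _window_mean(track: TimeSeries, t_lo: float, t_hi: float) -> float:
    t = track.times()
    sel = (t >= t_lo) & (t < t_hi)
    if not np.any(sel):
        return math.nan
    return float(np.nanmean(track.values[sel]))


def clamp_ratios(run: SimRun, clamp_window: tuple[float, float] | None = None,
                 flank_s: float = 1.0, seg_len_ms: float = 200.0,
                 overlap_frac: float = 0.75,
                 band: tuple[float, float] = (20.0, 120.0)) -> SpectralSummary:
    """F and P ratios between the clamp window and its 1 s flanks.

    The unclamped estimates average the tracks over ``flank_s`` before
    and after the clamp window; flanks that would run off the trace (or
    into the pre-ramp silence) are shrunk, with a warning recorded in
    the summary metadata.
    """
    window = clamp_window if clamp_window is not None else run.protocol.clamp_window
    w0, w1 = window
    if not w1 > w0:
        raise ValueError("clamp window is empty")
    ftrack, ptrack = instantaneous_freq_power(run.lfp, seg_len_ms, overlap_frac, band)
    meta: dict = {"clamp_window": [w0, w1]}
    t_start = run.lfp.t0 + (seg_len_ms * 1e-3) / 2
    t_end = run.lfp.t0 + run.lfp.duration - (seg_len_ms * 1e-3) / 2
    pre_lo = w0 - flank_s
    if pre_lo < t_start:
        pre_lo = t_start
        meta["flank_warning"] = "pre-clamp flank shrunk to fit trace"
    post_hi = w1 + flank_s
    if post_hi > t_end:
        post_hi = t_end
        meta["flank_warning"] = "post-clamp flank shrunk to fit trace"

    f_c = _window_mean(ftrack, w0, w1)
    p_c = _window_mean(ptrack, w0, w1)
    f_pre, f_post = _window_mean(ftrack, pre_lo, w0), _window_mean(ftrack, w1, post_hi)
    p_pre, p_post = _window_mean(ptrack, pre_lo, w0), _window_mean(ptrack, w1, post_hi)
    f_u = np.nanmean([f_pre, f_post])
    p_u = np.nanmean([p_pre, p_post])
    return SpectralSummary(ftrack, ptrack, f_c, float(f_u), p_c, float(p_u), meta)


def led_lfp_phase(lfp: TimeSeries, led: TimeSeries,
                  window: tuple[float, float] | None = None,
                  seg_len_ms: float = 500.0,
                  band: tuple[float, float] = (5.0, 200.0)) -> float:
    """LED–LFP phase difference (degrees) from the Welch cross-spectrum.

    The phase is read at the frequency bin of maximal cross-spectral
    magnitude within ``band``.  Positive values mean the LED command is
    phase-advanced relative to the LFP.
    """
    x, y = lfp, led
    if window is not None:
        x, y = lfp.slice(*window), led.slice(*window)
    if np.ptp(x.values) == 0 or np.ptp(y.values) == 0:
        raise ValueError("degenerate (constant) input to cross-spectrum")
    nperseg = min(int(round(seg_len_ms * 1e-3 * x.fs)), x.n)
    f, pxy = sps.csd(x.values, y.values, fs=x.fs, window="hann",
                     nperseg=nperseg, noverlap=nperseg // 2)
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel):
        raise ValueError("no cross-spectrum bins inside band")
    k = np.argmax(np.abs(pxy[sel]))
    # scipy csd(x, y) = conj(X)*Y: a LED that lags the LFP by d gives
    # angle -w*d, so the angle is directly the LED advance.
    return float(np.degrees(np.angle(pxy[sel][k])))
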