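"""Spike detection, per-spike LFP phase, and circular statistics.

Spike phase is estimated by passing a 200 ms segment of the LFP
centered on the spike through a Hann window and extracting the
dominant in-band tone's frequency and phase at the segment center.
Phases follow the package convention: LFP trough = 0°, increasing
through the cycle, range [0°, 360°); a "phase advance" is a shift
toward smaller phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import PhaseVector, SpikeTrain, TimeSeries, wrap_deg

__all__ = [
    "detect_spikes",
    "spike_phase",
    "spike_phase_table",
    "circular_mean",
    "sign_test",
    "hotelling_paired_vector_test",
    "vonmises_resultant_length",
]


def detect_spikes(trace: TimeSeries, threshold: float,
                  refractory_ms: float = 2.0) -> SpikeTrain:
    """Threshold-crossing spike times with a refractory constraint.

    The crossing direction follows the sign of ``threshold`` (negative
    thresholds catch downward-going events, as in cell-attached
    current recordings).  Crossings closer than ``refractory_ms`` to
    the previous accepted spike are discarded.  A crossing rate above
    100 Hz suggests the threshold sits in the noise floor; the train
    is still returned but carries a warning in ``source``.
    """
    x = trace.values
    if threshold >= 0:
        crossings = np.nonzero((x[1:] >= threshold) & (x[:-1] < threshold))[0] + 1
    else:
        crossings = np.nonzero((x[1:] <= threshold) & (x[:-1] > threshold))[0] + 1
    refr = refractory_ms * 1e-3 / trace.dt
    kept: list[int] = []
    last = -math.inf
    for i in crossings:
        if i - last >= refr:
            kept.append(int(i))
            last = i
    times = trace.t0 + np.asarray(kept, dtype=float) * trace.dt
    source = "detected"
    if len(kept) / trace.duration > 100.0:
        source = "detected[warning: crossing rate > 100 Hz]"
    return SpikeTrain(times, source=source)


def spike_phase(lfp: TimeSeries, t_spike: float, seg_ms: float = 200.0,
                band: tuple[float, float] = (20.0, 120.0)) -> tuple[float, float]:
    """LFP phase (degrees, trough = 0°) and frequency at one spike time.

    Raises ValueError when the segment does not fit inside the trace;
    callers batching many spikes should use :func:`spike_phase_table`,
    which records exclusion reasons instead.
    """
    half = int(round(seg_ms * 1e-3 / lfp.dt / 2))
    c = int(round((t_spike - lfp.t0) / lfp.dt))
    if c - half < 0 or c + half > lfp.n:
        raise ValueError("spike segment extends beyond the trace")
    seg = lfp.values[c - half:c + half]
    n = seg.size
    w = np.hanning(n)
    xw = (seg - seg.mean()) * w
    nfft = 1 << int(np.ceil(np.log2(n * 8)))
    spec = np.fft.rfft(xw, nfft)
    f = np.fft.rfftfreq(nfft, lfp.dt)
    sel = (f >= band[0]) & (f <= band[1])
    mag = np.abs(spec[sel])
    j = np.nonzero(sel)[0][int(np.argmax(mag))]
    la, lb, lc = np.log(np.abs(spec[j - 1:j + 2]) + 1e-300)
    denom = la - 2 * lb + lc
    delta = float(np.clip(0.5 * (la - lc) / denom if denom != 0 else 0.0, -0.5, 0.5))
    f_hat = f[j] + delta * (f[1] - f[0])
    # phase of the tone at the segment center (= spike time): project
    # onto a complex exponential on a time axis centered on the spike
    t_rel = lfp.t0 + (c - half + np.arange(n)) * lfp.dt - t_spike
    alpha = np.angle(np.sum(w * seg * np.exp(-2j * math.pi * f_hat * t_rel)))
    # cosine-argument alpha has the LFP peak at 0; trough convention
    phase = wrap_deg(math.degrees(alpha) + 180.0)
    return (float(phase), float(f_hat))


def spike_phase_table(lfp: TimeSeries, spikes: SpikeTrain | np.ndarray,
                      seg_ms: float = 200.0,
                      band: tuple[float, float] = (20.0, 120.0)):
    """Per-spike phase/frequency table as a pandas DataFrame.

    Spikes whose segment falls off the trace are kept with NaN values
    and an exclusion reason code.
    """
    import pandas as pd

    times = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    rows = []
    for t in times:
        try:
            ph, fr = spike_phase(lfp, float(t), seg_ms, band)
            rows.append((t, ph, fr, "ok"))
        except ValueError:
            rows.append((t, math.nan, math.nan, "edge"))
    return pd.DataFrame(rows, columns=["time_s", "phase_deg", "freq_hz", "status"])


def circular_mean(phases_deg) -> PhaseVector:
    """Mean resultant vector of unit phasors.

    R = |mean(exp(i*phase))| is the vector length in [0, 1]; the angle
    is the circular mean direction.
    """
    phases = np.asarray(phases_deg, dtype=float)
    if phases.size == 0:
        raise ValueError("circular_mean of an empty phase list")
    z = np.exp(1j * np.deg2rad(phases)).mean()
    return PhaseVector.from_cartesian(z.real, z.imag)


def sign_test(paired_deltas) -> float:
    """Exact two-sided binomial sign test; zero differences are dropped."""
    d = np.asarray(paired_deltas, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("sign test undefined: all differences are ties")
    n_pos = int((d > 0).sum())
    return float(stats.binomtest(n_pos, d.size, 0.5).pvalue)


def hotelling_paired_vector_test(vectors_before, vectors_after,
                                 weighted: bool = True) -> float:
    """Paired Hotelling T² on phase-vector differences.

    Each vector is mapped to Cartesian components (R·cos, R·sin) —
    unit vectors instead when ``weighted`` is False — and the paired
    component differences are tested against zero mean with the
    one-sample Hotelling T² (F reference with p = 2 dimensions).
    Identical pairs (all-zero differences) are reported as p = 1.
    """
    if len(vectors_before) != len(vectors_after):
        raise ValueError("paired test needs equal-length vector lists")
    n = len(vectors_before)
    if n < 3:
        raise ValueError("Hotelling test needs at least 3 pairs")

    def comp(v: PhaseVector):
        x, y = v.cartesian()
        if not weighted and v.magnitude > 0:
            x, y = x / v.magnitude, y / v.magnitude
        return (x, y)

    d = np.array([np.subtract(comp(a), comp(b))
                  for a, b in zip(vectors_after, vectors_before)])
    if np.allclose(d, 0.0):
        return 1.0
    mean = d.mean(axis=0)
    cov = np.cov(d.T, ddof=1)
    try:
        t2 = n * mean @ np.linalg.solve(cov, mean)
    except np.linalg.LinAlgError:
        return 1.0 if np.allclose(mean, 0) else 0.0
    p_dim = 2
    f_stat = (n - p_dim) / (p_dim * (n - 1)) * t2
    return float(stats.f.sf(f_stat, p_dim, n - p_dim))


def vonmises_resultant_length(kappa: float) -> float:
    """Theoretical mean resultant length A(kappa) = I1(kappa)/I0(kappa)."""
    from scipy.special import i0, i1
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))
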