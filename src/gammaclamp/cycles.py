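"""Cycle-aligned analysis of membrane currents against the LFP.

Successive LFP troughs delimit gamma cycles; cycles whose period
deviates more than 20% from the modal period are rejected.  The
membrane current between accepted troughs is expressed as a function
of instantaneous phase (linear from 0° at one trough to 360° at the
next), averaged over cycles, reduced to its phasic component by
subtracting the per-cycle-average minimum (holding-potential aware),
and summarised as a phase vector.  Vector differences between clamped
and unclamped epochs give the net imposed currents ΔE and ΔI;
conductances follow from Ohm's law at a fixed driving force, and the
excitation–inhibition orbit traces (g_e, g_i) over the cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import CycleAverage, CycleSet, PhaseVector, TimeSeries, wrap_deg

__all__ = [
    "detect_troughs",
    "accept_cycles",
    "cycle_average",
    "phasic_component",
    "current_vector",
    "delta_vector",
    "conductance",
    "ei_orbit",
]


def detect_troughs(lfp: TimeSeries, band: tuple[float, float] = (20.0, 120.0),
                   min_period_frac: float = 0.5) -> np.ndarray:
    """Indices of successive LFP troughs (local minima of the band-passed trace).

    A zero-phase Butterworth band-pass isolates the oscillation, local
    minima are found with a minimum separation of ``min_period_frac``
    times the dominant period, and the indices refer to the raw trace
    grid.  Returns an empty array when no oscillatory content stands
    above the noise floor.
    """
    x = lfp.values - lfp.values.mean()
    nyq = 0.5 * lfp.fs
    sos = sps.butter(3, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    xf = sps.sosfiltfilt(sos, x)
    rms = float(np.sqrt(np.mean(xf ** 2)))
    if rms < 1e-12 or rms < 1e-3 * (np.abs(x).max() + 1e-300):
        return np.array([], dtype=int)
    # dominant period from the autocorrelation-free route: spectral peak
    f, pxx = sps.welch(xf, fs=lfp.fs, nperseg=min(4096, xf.size))
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any() or pxx[sel].max() <= 0:
        return np.array([], dtype=int)
    f_dom = f[sel][np.argmax(pxx[sel])]
    min_sep = max(1, int(round(min_period_frac / f_dom * lfp.fs)))
    troughs, _ = sps.find_peaks(-xf, distance=min_sep, prominence=0.5 * rms)
    return troughs.astype(int)


def accept_cycles(troughs: np.ndarray, tolerance: float = 0.20,
                  dt: float = 1e-4, hist_bin_ms: float = 1.0) -> CycleSet:
    """Flag cycles whose period deviates from the modal period.

    The modal period is the densest 1 ms bin of the inter-trough
    interval histogram; a cycle is accepted when its period deviates by
    at most ``tolerance`` (fraction, boundary inclusive) from the mode.
    """
    troughs = np.asarray(troughs, dtype=int)
    if troughs.size < 4:
        raise ValueError("need at least 3 cycles (4 troughs) to define a modal period")
    periods = np.diff(troughs) * dt
    bin_s = hist_bin_ms * 1e-3
    edges = np.arange(periods.min() - bin_s, periods.max() + 2 * bin_s, bin_s)
    counts, edges = np.histogram(periods, bins=edges)
    modal = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    accepted = np.abs(periods - modal) <= tolerance * modal
    return CycleSet(troughs, float(modal), accepted, tolerance, dt)


def cycle_average(current: TimeSeries, cycles: CycleSet, n_bins: int = 64,
                  holding_mv: float | None = None) -> CycleAverage:
    """Mean current per phase bin over all accepted cycles.

    Each accepted cycle (trough to trough) is resampled by linear
    interpolation onto ``n_bins`` uniform phase bins covering
    [0°, 360°), then averaged arithmetically across cycles.
    """
    if cycles.n_accepted == 0:
        raise ValueError("no accepted cycles to average")
    phase_grid = np.arange(n_bins) / n_bins  # fraction of cycle, bin left edges
    acc = np.zeros(n_bins)
    idx = cycles.trough_indices
    x = current.values
    n_used = 0
    for c in range(cycles.n_cycles):
        if not cycles.accepted[c]:
            continue
        i0, i1 = idx[c], idx[c + 1]
        if i1 >= x.size:
            continue
        samp = i0 + phase_grid * (i1 - i0)
        acc += np.interp(samp, np.arange(i0, i1 + 1), x[i0:i1 + 1])
        n_used += 1
    if n_used == 0:
        raise ValueError("no accepted cycles lie fully inside the trace")
    return CycleAverage(phase_grid * 360.0, acc / n_used, n_used,
                        units=current.units, holding_mv=holding_mv)


def phasic_component(avg: CycleAverage, holding_mv: float | None = None) -> CycleAverage:
    """Phasic current: cycle average minus its per-cycle extremum.

    At −70 mV (excitatory currents, inward/negative) the *least
    negative* value is subtracted and the result reported as a
    positive magnitude; at 0 mV (inhibitory currents, outward) the
    minimal outward current is subtracted.  Either way the phasic
    component is ≥ 0 with its holding potential recorded.
    """
    hold = holding_mv if holding_mv is not None else avg.holding_mv
    vals = avg.mean_current
    if hold is not None and hold < -35.0:
        phasic = vals.max() - vals  # inward: least-negative baseline removed
    else:
        phasic = vals - vals.min()
    return CycleAverage(avg.phase_bins_deg.copy(), phasic, avg.n_cycles,
                        units=avg.units, holding_mv=hold)


def current_vector(phasic: CycleAverage) -> PhaseVector:
    """Amplitude-weighted circular mean of the phasic current.

    The angle is the circular mean of bin phases weighted by phasic
    amplitude; the magnitude is the mean phasic amplitude (pA).  An
    all-zero phasic waveform yields a zero vector with the angle
    flagged undefined.
    """
    w = phasic.mean_current
    total = w.sum()
    if total <= 0:
        return PhaseVector(0.0, 0.0, angle_defined=False)
    ang = np.deg2rad(phasic.phase_bins_deg)
    z = np.sum(w * np.exp(1j * ang)) / total
    if abs(z) < 1e-12:
        return PhaseVector(0.0, 0.0, angle_defined=False)
    return PhaseVector(float(w.mean()), math.degrees(math.atan2(z.imag, z.real)))


def delta_vector(clamped: PhaseVector, unclamped: PhaseVector) -> PhaseVector:
    """Net imposed current: Cartesian difference clamped − unclamped."""
    cx, cy = clamped.cartesian()
    ux, uy = unclamped.cartesian()
    return PhaseVector.from_cartesian(cx - ux, cy - uy)


def conductance(current: TimeSeries | CycleAverage,
                driving_force_mv: float = 70.0):
    """Ohm's-law conductance |I| / driving force, elementwise (pA/mV = nS)."""
    if driving_force_mv <= 0:
        raise ValueError("driving force must be positive")
    if isinstance(current, CycleAverage):
        return CycleAverage(current.phase_bins_deg.copy(),
                            np.abs(current.mean_current) / driving_force_mv,
                            current.n_cycles, units="nS",
                            holding_mv=current.holding_mv)
    return current.copy_with(np.abs(current.values) / driving_force_mv, units="nS")


@dataclass
class EIOrbit:
    """Closed (g_e, g_i) orbit over phase bins, anchored at the trough."""

    phase_deg: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    direction: str  # 'ccw' | 'cw' | 'degenerate'
    signed_area: float


def ei_orbit(g_exc: CycleAverage, g_inh: CycleAverage) -> EIOrbit:
    """Phasic inhibition against phasic excitation over the cycle.

    The orbit is anchored at phase 0° (LFP trough) and its traversal
    direction is the sign of the shoelace area: counter-clockwise
    (positive area) when excitation leads inhibition.
    """
    if g_exc.n_bins != g_inh.n_bins:
        raise ValueError("conductance cycle averages must share the bin grid")
    x, y = g_exc.mean_current, g_inh.mean_current
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    scale = (np.ptp(x) * np.ptp(y)) or 1.0
    if abs(area) < 1e-9 * scale:
        direction = "degenerate"
    else:
        direction = "ccw" if area > 0 else "cw"
    return EIOrbit(g_exc.phase_bins_deg.copy(), x.copy(), y.copy(), direction, area)
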