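"""Phase response curves and closed-loop frequency-shift prediction.

The PRC of an oscillating plant is measured empirically: a brief
"kick" is added to the drive at a controlled phase of the ongoing
oscillation and the asymptotic phase shift of subsequent cycles is
read against an unperturbed twin run integrated with the same noise
realization.  The circular cross-correlogram of the PRC with the LFP
cycle waveform then predicts how a *continuous* closed-loop modulation
at any phase offset changes the oscillation frequency, which
:func:`validate_prediction` checks against directly simulated clamp
sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import RampProtocol, TimeSeries, circdiff_deg, wrap_deg
from .spikes import spike_phase
from .synth import run_open_loop

__all__ = ["PRC", "measure_prc", "predict_freq_shift", "validate_prediction"]


@dataclass
class PRC:
    """Phase response curve: phase shift (degrees, advance positive)
    per unit (kick amplitude x duration in ms), on a phase grid with
    the LFP trough at 0°."""

    phases_deg: np.ndarray
    shift: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.phases_deg = np.asarray(self.phases_deg, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        if not np.all(np.isfinite(self.shift)):
            raise ValueError("PRC contains non-finite shifts")

    def __call__(self, phases_deg) -> np.ndarray:
        """Periodic linear interpolation of the curve."""
        p = np.mod(np.asarray(phases_deg, dtype=float), 360.0)
        xp = np.concatenate([self.phases_deg, [self.phases_deg[0] + 360.0]])
        fp = np.concatenate([self.shift, [self.shift[0]]])
        return np.interp(p, xp, fp)


def _phase_at(lfp: TimeSeries, t: float, seg_ms: float, band) -> float:
    ph, _ = spike_phase(lfp, t, seg_ms=seg_ms, band=band)
    return ph


def measure_prc(plant_factory, baseline_drive: TimeSeries, kick_amplitude: float,
                kick_duration_ms: float = 1.0, n_phases: int = 16, n_reps: int = 1,
                seed: int = 0, settle_cycles: float = 5.0,
                t_kick_center: float | None = None,
                band: tuple[float, float] = (20.0, 120.0),
                seg_ms: float = 200.0, use_raw_lfp: bool = True) -> PRC:
    """Empirical PRC by transient perturbation against twin runs.

    ``plant_factory()`` must return a fresh plant; each perturbed run
    shares its seed (and hence noise realization) with an unperturbed
    twin, so the measured shift isolates the kick.  Kicks are
    rectangular pulses added to ``baseline_drive``, timed so that the
    unperturbed oscillation sits at each target phase; the shift is the
    circular difference of tone phases ``settle_cycles`` after the
    kick, averaged over ``n_reps`` repetitions on successive cycles.
    """
    dt = baseline_drive.dt

    def obs(run) -> TimeSeries:
        # phases are referenced to the plant-side LFP when available so
        # the curve is not rotated by the acquisition-filter lag
        if use_raw_lfp and "lfp_raw" in run.extras:
            return run.lfp.copy_with(run.extras["lfp_raw"])
        return run.lfp

    ref = run_open_loop(plant_factory(), baseline_drive, seed)
    if ref.meta.get("oscillating") is False:
        raise ValueError("plant is not oscillating under the baseline drive")
    ref_lfp = obs(ref)
    t_total = baseline_drive.duration
    t_center = t_kick_center if t_kick_center is not None else 0.5 * t_total
    # local period and phase of the unperturbed oscillation at t_center
    ph_c, f0 = spike_phase(ref_lfp, t_center, seg_ms=seg_ms, band=band)
    period = 1.0 / f0
    if ref_lfp.values[int(0.25 * ref_lfp.n):].std() < 1e-12:
        raise ValueError("plant is not oscillating under the baseline drive")

    n_kick = max(1, int(round(kick_duration_ms * 1e-3 / dt)))
    targets = np.arange(n_phases) * (360.0 / n_phases)
    shifts = np.zeros(n_phases)
    for k, target in enumerate(targets):
        acc = 0.0
        for rep in range(n_reps):
            # kick time: when the reference oscillation reaches the target
            # phase, rep cycles after t_center
            dphi = wrap_deg(target - ph_c)
            t_kick = t_center + (dphi / 360.0 + rep) * period
            # rectangular pulse centered on the target phase
            i_kick = int(round((t_kick - baseline_drive.t0) / dt - n_kick / 2))
            drive2 = baseline_drive.values.copy()
            drive2[i_kick:i_kick + n_kick] += kick_amplitude
            pert = run_open_loop(
                plant_factory(), baseline_drive.copy_with(drive2), seed)
            t_meas = t_kick + settle_cycles * period + seg_ms * 1e-3 / 2
            ph_p = _phase_at(obs(pert), t_meas, seg_ms, band)
            ph_u = _phase_at(ref_lfp, t_meas, seg_ms, band)
            acc += circdiff_deg(ph_p, ph_u)
        shifts[k] = acc / n_reps
    norm = kick_amplitude * kick_duration_ms
    return PRC(targets, shifts / norm if norm != 0 else shifts,
               meta={"f0_hz": f0, "kick_amplitude": kick_amplitude,
                     "kick_duration_ms": kick_duration_ms, "seed": seed,
                     "n_reps": n_reps})


def predict_freq_shift(prc: PRC, waveform, period_s: float | None = None,
                       offsets_deg: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Circular cross-correlogram of PRC and LFP waveform.

    For each offset theta the predicted per-cycle phase shift is the
    cycle average of ``PRC(phi) * waveform(phi - theta)`` times the
    cycle duration in ms (the PRC is normalized per amplitude x ms);
    dividing by 360° gives the predicted fractional frequency change.
    Returns ``(offsets_deg, fractional_shift)``.  With no ``period_s``
    the result is left in per-cycle phase-shift units per 360°,
    proportional to the fractional change.
    """
    if offsets_deg is None:
        offsets_deg = np.arange(0.0, 360.0, 5.0)
    offsets_deg = np.asarray(offsets_deg, dtype=float)
    phi = np.arange(0.0, 360.0, 2.5)
    if hasattr(waveform, "phase_bins_deg"):
        wx, wy = waveform.phase_bins_deg, waveform.mean_current
    else:
        wx, wy = waveform
        wx = np.asarray(wx, dtype=float)
        wy = np.asarray(wy, dtype=float)
    xp = np.concatenate([wx, [wx[0] + 360.0]])
    fp = np.concatenate([wy, [wy[0]]])

    def wave(p):
        return np.interp(np.mod(p, 360.0), xp, fp)

    prc_vals = prc(phi)
    out = np.empty(offsets_deg.size)
    for i, th in enumerate(offsets_deg):
        out[i] = np.mean(prc_vals * wave(phi - th))
    period_ms = 1000.0 * (period_s if period_s is not None
                          else 1.0 / prc.meta.get("f0_hz", 1000.0 / 360.0))
    return offsets_deg, out * period_ms / 360.0


def validate_prediction(measured_phases_deg, measured_fshift,
                        prc: PRC, waveform, period_s: float | None = None):
    """Compare a directly simulated frequency-shift-versus-phase curve
    with the PRC x waveform prediction.

    ``measured_phases_deg`` are LED phase advances; the prediction is
    evaluated at matching waveform offsets (an advance by psi is an
    offset of -psi).  Returns a report dict with the Pearson
    correlation, the best-fit gain, the circular peak-phase mismatch,
    and a linearity flag.
    """
    phases = np.asarray(measured_phases_deg, dtype=float)
    meas = np.asarray(measured_fshift, dtype=float)
    _, pred = predict_freq_shift(prc, waveform, period_s, offsets_deg=-phases)
    if np.std(pred) == 0 or np.std(meas) == 0:
        raise ValueError("degenerate curves: no variation to correlate")
    r = float(np.corrcoef(meas, pred)[0, 1])
    gain = float(np.dot(meas, pred) / np.dot(pred, pred))
    peak_mismatch = float(circdiff_deg(phases[int(np.argmax(meas))],
                                       phases[int(np.argmax(pred))]))
    return {
        "pearson_r": r,
        "gain": gain,
        "peak_phase_mismatch_deg": peak_mismatch,
        "linear_regime": bool(r >= 0.9),
        "predicted": pred,
        "measured": meas,
        "phases_deg": phases,
    }
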