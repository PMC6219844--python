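"""Canonical study conditions and figure-level reproductions.

This module freezes the reference configurations under which the
package's headline properties are demonstrated and tested:

* a Stuart–Landau clamp sweep (rotation of the (ΔF, ΔP) vector with
  feedback phase, against the averaged rotating-frame theory),
* a PRC measurement on the Stuart–Landau plant with the circular
  cross-correlogram prediction of the frequency-shift-versus-phase
  curve,
* an E–I mass-model clamp battery (power-raising clamp tightens spike
  synchrony at constant mean rate; frequency-raising clamp advances
  spike phase; the imposed excitatory-current phase sorts frequency
  and power effects).

Every entry point takes a master seed and returns plain dictionaries
of measured numbers, so the same code backs the test-suite, the
acceptance script and the examples.
"""

from __future__ import annotations

import math

import numpy as np

from .controller import ControllerConfig, OpsinModel, run_closed_loop
from .core import RampProtocol, TimeSeries, circdiff_deg
from .cycles import delta_vector
from .pipeline import epoch_current_vector
from .prc import measure_prc, validate_prediction
from .spectral import clamp_ratios, led_lfp_phase
from .spikes import circular_mean, spike_phase_table
from .synth import (EIMassParams, EIMassPlant, MeasurementModel,
                    StuartLandauParams, StuartLandauPlant)
from .theory import analytic_prc, averaged_clamp_response, phase_to_gains
from .cycles import accept_cycles, cycle_average, detect_troughs

__all__ = [
    "sl_study_params",
    "sl_study_protocol",
    "sl_study_opsin",
    "run_sl_rotation_sweep",
    "run_sl_prc_study",
    "ei_study_protocol",
    "run_ei_clamp_battery",
    "zero_crossings_deg",
    "quadrant_traversal",
]

# ---------------------------------------------------------------------------
# Stuart–Landau reference configuration
# ---------------------------------------------------------------------------

SL_F0_HZ = 40.0
SL_GAIN_PER_MV = 0.6  # weak-feedback modulation depth ~0.2 at 0.3 mV LFP


def sl_study_params(noise_sigma: float = 0.0) -> StuartLandauParams:
    """Hopf plant at its clamp-study working point (40 Hz, mu/omega ~ 0.2).

    The sweep and PRC studies run at mu = 50/s so the amplitude and
    phase responses to feedback are in near-quadrature (the observed
    power curve is rotated against the radius response by
    atan(mu/omega), kept small here); the closed-form amplitude and
    frequency checks use mu = 100 as their own configuration.
    """
    return StuartLandauParams(mu=50.0, drive_gain=1500.0,
                              noise_sigma=noise_sigma)


def sl_study_protocol() -> RampProtocol:
    return RampProtocol(duration_s=8.0, clamp_window=(4.0, 6.0))


def sl_study_opsin() -> OpsinModel:
    # symmetric kinetics at the reference point so the small-signal
    # opsin response used by the averaged theory is exact
    return OpsinModel(tau_on_ms=6.0, tau_off_ms=6.0)


def zero_crossings_deg(phases_deg: np.ndarray, values: np.ndarray) -> list[float]:
    """Linearly interpolated zero crossings of a cyclic curve."""
    phases = np.asarray(phases_deg, dtype=float)
    vals = np.asarray(values, dtype=float)
    out = []
    n = len(vals)
    for i in range(n):
        a, b = vals[i], vals[(i + 1) % n]
        pa = phases[i]
        pb = phases[(i + 1) % n] if i + 1 < n else phases[0] + 360.0
        if a == 0.0:
            out.append(pa % 360.0)
        elif a * b < 0:
            out.append((pa + (pb - pa) * abs(a) / (abs(a) + abs(b))) % 360.0)
    return out


def quadrant_traversal(df: np.ndarray, dp: np.ndarray) -> tuple[int, int]:
    """(number of distinct quadrants, number of sign-change transitions)
    of the (ΔF, ΔP) vector over one cyclic sweep."""
    quads = [(int(np.sign(f)), int(np.sign(p))) for f, p in zip(df, dp)]
    distinct = len(set(quads))
    transitions = sum(1 for i in range(len(quads))
                      if quads[i] != quads[(i + 1) % len(quads)])
    return distinct, transitions


def run_sl_rotation_sweep(seed: int = 1, n_phases: int = 12,
                          gain_per_mv: float = SL_GAIN_PER_MV) -> dict:
    """Clamp sweep over feedback phase on the Hopf plant.

    Returns measured and theory-predicted ΔF = F_c/F_u − 1 and
    ΔP = P_c/P_u − 1 at each requested feedback phase, relative L2
    errors, quadrant traversal counts, and the separation of the ΔF
    and ΔP zero crossings.
    """
    params = sl_study_params()
    prot = sl_study_protocol()
    opsin = sl_study_opsin()
    meas = MeasurementModel()
    psis = np.arange(n_phases) * (360.0 / n_phases)
    ramp_mid = 0.5 * (prot.clamp_window[0] + prot.clamp_window[1]) / prot.duration_s
    rows = {"psi_deg": psis, "df": [], "dp": [], "df_pred": [], "dp_pred": [],
            "drive_phase_deg": []}
    for psi in psis:
        k1, k2 = phase_to_gains(psi, gain_per_mv, SL_F0_HZ)
        cfg = ControllerConfig(k1=k1, k2=k2)
        run = run_closed_loop(StuartLandauPlant(params, measurement=meas),
                              cfg, opsin, prot, seed)
        summ = clamp_ratios(run)
        pred = averaged_clamp_response(params, cfg, opsin, meas,
                                       ramp_value=ramp_mid * prot.ramp_peak_command)
        rows["df"].append(summ.f_ratio - 1.0)
        rows["dp"].append(summ.p_ratio - 1.0)
        rows["df_pred"].append(pred["f_ratio"] - 1.0)
        rows["dp_pred"].append(pred["p_ratio"] - 1.0)
        raw = run.lfp.copy_with(run.extras["lfp_raw"])
        inner = (prot.clamp_window[0] + 0.1, prot.clamp_window[1] - 0.1)
        rows["drive_phase_deg"].append(
            led_lfp_phase(raw, run.opsin_drive, window=inner))
    for k in ("df", "dp", "df_pred", "dp_pred", "drive_phase_deg"):
        rows[k] = np.asarray(rows[k])

    out = dict(rows)
    out["rel_l2_err_f"] = float(np.linalg.norm(rows["df"] - rows["df_pred"])
                                / np.linalg.norm(rows["df_pred"]))
    out["rel_l2_err_p"] = float(np.linalg.norm(rows["dp"] - rows["dp_pred"])
                                / np.linalg.norm(rows["dp_pred"]))
    out["n_quadrants"], out["n_transitions"] = quadrant_traversal(rows["df"], rows["dp"])
    zf = zero_crossings_deg(psis, rows["df"])
    zp = zero_crossings_deg(psis, rows["dp"])
    seps = [min(abs(circdiff_deg(a, b)) for b in zp) for a in zf]
    out["zero_crossing_sep_deg"] = float(np.mean(seps)) if seps else math.nan
    return out


def run_sl_prc_study(seed: int = 1, n_phases: int = 16,
                     kick_amplitude: float = 0.05,
                     rotation: dict | None = None) -> dict:
    """PRC measurement on the Hopf plant plus the Fig-3d-style check.

    Measures the empirical PRC against the closed-form radial-isochron
    PRC, then correlates the circular cross-correlogram prediction with
    the directly simulated frequency shifts of the rotation sweep.
    """
    params = sl_study_params()
    meas = MeasurementModel()
    drive = TimeSeries(np.zeros(30000), 1e-4, "V")

    def factory():
        return StuartLandauPlant(params, measurement=meas)

    prc = measure_prc(factory, drive, kick_amplitude=kick_amplitude,
                      kick_duration_ms=1.0, n_phases=n_phases, seed=seed)
    ana = analytic_prc(params, prc.phases_deg,
                       kick_amplitude=kick_amplitude, kick_duration_ms=1.0)
    out = {
        "prc_phases_deg": prc.phases_deg,
        "prc_measured": prc.shift,
        "prc_analytic": ana,
        "prc_rel_l2_err": float(np.linalg.norm(prc.shift - ana)
                                / np.linalg.norm(ana)),
        "f0_hz": prc.meta["f0_hz"],
    }
    if rotation is None:
        rotation = run_sl_rotation_sweep(seed)
    # cycle-averaged unclamped LFP waveform (raw, zero-mean)
    prot = sl_study_protocol()
    ref = run_closed_loop(factory(), ControllerConfig(), sl_study_opsin(),
                          prot, seed)
    raw = ref.lfp.copy_with(ref.extras["lfp_raw"]).slice(2.0, 4.0)
    cset = accept_cycles(detect_troughs(raw))
    wav = cycle_average(raw, cset)
    wav.mean_current = wav.mean_current - wav.mean_current.mean()
    report = validate_prediction(rotation["drive_phase_deg"], rotation["df"],
                                 prc, wav, period_s=1.0 / out["f0_hz"])
    out["prediction_r"] = report["pearson_r"]
    out["prediction_gain"] = report["gain"]
    return out


# ---------------------------------------------------------------------------
# E–I mass-model reference configuration
# ---------------------------------------------------------------------------

EI_F0_HZ = 31.0           # plateau gamma frequency of the default E–I plant
EI_GAIN_PER_MV = 0.3
EI_PSI_POWER_UP = 270.0   # feedback phase raising oscillation power
EI_PSI_FREQ_UP = 45.0     # feedback phase raising oscillation frequency
EI_WINDOW = (5.0, 7.0)


def ei_study_protocol() -> RampProtocol:
    """8 s ramp saturating at 4 s so the clamp window and its flanks sit
    on a stationary gamma plateau."""
    return RampProtocol(duration_s=8.0, clamp_window=EI_WINDOW,
                        ramp_plateau_s=4.0, ramp_peak_command=1.0)


def _ei_run(psi_deg: float | None, seed: int) -> "SimRun":
    if psi_deg is None:
        cfg = ControllerConfig()
    else:
        k1, k2 = phase_to_gains(psi_deg, EI_GAIN_PER_MV, EI_F0_HZ)
        cfg = ControllerConfig(k1=k1, k2=k2)
    return run_closed_loop(EIMassPlant(EIMassParams(),
                                       measurement=MeasurementModel()),
                           cfg, OpsinModel(), ei_study_protocol(), seed)


def _pooled_spike_stats(runs, window) -> dict:
    phases = []
    n = 0
    for run in runs:
        times = np.sort(np.concatenate([s.spike_times for s in run.spikes]))
        sel = times[(times >= window[0]) & (times < window[1])]
        n += sel.size
        tab = spike_phase_table(run.lfp, sel)
        ok = tab[tab.status == "ok"]
        phases.extend(ok.phase_deg.values)
    pv = circular_mean(phases)
    n_cells = len(runs[0].spikes)
    dur = (window[1] - window[0]) * len(runs) * n_cells
    return {"R": pv.magnitude, "mean_phase_deg": pv.angle_deg,
            "n_spikes": n, "rate_hz": n / dur}


def run_ei_clamp_battery(seed: int = 1, n_trials: int = 4) -> dict:
    """Clamped versus unclamped-twin trials on the E–I plant.

    Runs ``n_trials`` trials each of: unclamped twins, a power-raising
    clamp, and a frequency-raising clamp (seeds derived from the master
    seed).  Spike phases are pooled across trials within the clamp
    window; spectral ratios and the net imposed excitatory-current
    vector ΔE are averaged across trials.
    """
    seeds = [int((seed * 613 + 31 * k) % (2 ** 31)) for k in range(n_trials)]
    out: dict = {"n_trials": n_trials}
    twins = [_ei_run(None, s) for s in seeds]
    out["unclamped"] = _pooled_spike_stats(twins, EI_WINDOW)
    for label, psi in (("power_up", EI_PSI_POWER_UP),
                       ("freq_up", EI_PSI_FREQ_UP)):
        runs = [_ei_run(psi, s) for s in seeds]
        f_ratios, p_ratios, des = [], [], []
        for run in runs:
            summ = clamp_ratios(run)
            f_ratios.append(summ.f_ratio)
            p_ratios.append(summ.p_ratio)
            try:
                v_c = epoch_current_vector(run, EI_WINDOW)
                v_u = epoch_current_vector(run, (4.0, EI_WINDOW[0]))
                des.append(delta_vector(v_c, v_u))
            except ValueError:
                pass
        st = _pooled_spike_stats(runs, EI_WINDOW)
        st["f_ratio"] = float(np.mean(f_ratios))
        st["p_ratio"] = float(np.mean(p_ratios))
        if des:
            z = np.mean([d.magnitude * np.exp(1j * np.deg2rad(d.angle_deg))
                         for d in des])
            st["dE_pA"] = float(abs(z))
            st["dE_phase_deg"] = float(np.degrees(np.angle(z)) % 360.0)
        base = out["unclamped"]
        st["delta_R"] = st["R"] - base["R"]
        st["delta_phase_deg"] = float(circdiff_deg(st["mean_phase_deg"],
                                                   base["mean_phase_deg"]))
        st["rate_change_frac"] = st["n_spikes"] / base["n_spikes"] - 1.0
        st["rate_2se_frac"] = 2.0 / math.sqrt(base["n_spikes"])
        out[label] = st
    return out
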