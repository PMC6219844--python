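"""Averaged (rotating-frame) theory for the clamped Hopf oscillator.

For weak periodic forcing of the Stuart–Landau oscillator, averaging
over one cycle gives closed-form predictions for the steady-state
changes in amplitude and frequency: writing the feedback force along
the drive direction e^{i*beta} as A*cos(phi + psi) (phi the oscillator
phase, psi the effective feedback phase after every filter in the
loop), the radial component shifts the amplitude by

    dR = A * cos(psi + beta) / (4*mu)

(relaxation rate 2*mu about the limit cycle of radius R0 = sqrt(mu)),
and the tangential component shifts the angular frequency by

    d(omega) = A * sin(psi + beta) / (2*R0)  [- 2*shear*R0*dR].

The module also provides the discrete transfer function of the whole
feedback chain (measurement band-pass, one-sample loop latency, the
k1/k2 mixing with its differencing-plus-boxcar derivative, and the
opsin low-pass), the pure-tone conversion between a requested feedback
phase and (k1, k2), and the analytic phase response curve of the
oscillator, all in the package's trough = 0 degree phase convention.
"""

from __future__ import annotations

import cmath
import math

from .controller import ControllerConfig, OpsinModel
from .core import wrap_deg
from .synth import MeasurementModel, StuartLandauParams

__all__ = [
    "phase_to_gains",
    "feedback_chain",
    "averaged_clamp_response",
    "analytic_prc",
]


def phase_to_gains(psi_deg: float, gain_per_mv: float, f0_hz: float) -> tuple[float, float]:
    """(k1, k2) realizing a pure-tone LED phase advance psi at f0.

    For a tone at f0, ``k1*LFP + k2*dLFP/dt`` equals
    ``K*A*cos(phase + psi)`` with ``K = sqrt(k1^2 + (k2*w)^2)`` and
    ``psi = atan2(k2*w, k1)`` (w in rad/ms).  Given a requested
    advance psi and total gain K (per mV), this inverts that relation.
    """
    w_ms = 2 * math.pi * f0_hz / 1000.0  # rad per ms
    psi = math.radians(psi_deg)
    k1 = gain_per_mv * math.cos(psi)
    k2 = gain_per_mv * math.sin(psi) / w_ms
    return (k1, k2)


def _one_pole(alpha: float, z_inv: complex) -> complex:
    """Discrete transfer of y[i] = y[i-1] + alpha*(x[i] - y[i-1])."""
    return alpha / (1.0 - (1.0 - alpha) * z_inv)


def feedback_chain(cfg: ControllerConfig, opsin: OpsinModel,
                   measurement: MeasurementModel, f_hz: float,
                   dt: float = 1e-4) -> complex:
    """Complex gain from raw plant LFP (mV) to opsin drive modulation,
    per unit ramp value, at frequency ``f_hz``.

    Includes the discrete measurement band-pass, the
    ``feedback_delay_steps`` loop latency, the k1 path, the k2 path
    (first difference in mV/ms followed by the trailing boxcar), and
    the opsin one-pole (symmetric-tau approximation for the
    small-signal response).
    """
    w = 2 * math.pi * f_hz
    z_inv = cmath.exp(-1j * w * dt)

    if measurement.enabled:
        a_hp = 1.0 - math.exp(-dt * 2 * math.pi * measurement.hp_hz)
        a_lp = 1.0 - math.exp(-dt * 2 * math.pi * measurement.lp_hz)
        h_meas = (1.0 - _one_pole(a_hp, z_inv)) * _one_pole(a_lp, z_inv)
    else:
        h_meas = 1.0 + 0.0j

    h_delay = z_inv ** cfg.feedback_delay_steps
    dt_ms = dt * 1000.0
    wlen = cfg.deriv_window_samples
    # first difference (per ms) then W-sample trailing boxcar
    h_deriv = (1.0 - z_inv ** wlen) / (wlen * dt_ms)
    h_ctrl = cfg.k1 + cfg.k2 * h_deriv

    tau_s = 0.5e-3 * (opsin.tau_on_ms + opsin.tau_off_ms)
    a_ops = 1.0 - math.exp(-dt / tau_s)
    h_ops = opsin.gain * _one_pole(a_ops, z_inv)

    return h_meas * h_delay * h_ctrl * h_ops


def averaged_clamp_response(params: StuartLandauParams, cfg: ControllerConfig,
                            opsin: OpsinModel, measurement: MeasurementModel,
                            ramp_value: float, dt: float = 1e-4):
    """Predicted (ΔF in Hz, ΔP/P) for a weak clamp on the Hopf plant.

    Returns a dict with the frequency shift, fractional power change,
    the effective feedback phase, and the predicted ratios relative to
    the unclamped oscillation.
    """
    if params.mu <= 0:
        raise ValueError("averaged theory needs an oscillating plant (mu > 0)")
    f0 = params.limit_cycle_freq_hz
    r0 = params.limit_cycle_radius
    h = feedback_chain(cfg, opsin, measurement, f0, dt)
    if params.drive_hp_hz is not None:
        w = 2 * math.pi * f0
        z_inv = cmath.exp(-1j * w * dt)
        a = 1.0 - math.exp(-dt * 2 * math.pi * params.drive_hp_hz)
        h *= 1.0 - _one_pole(a, z_inv)
    # LED modulation = ramp * h * LFP;  LFP = obs_gain * R0 * cos(phi)
    amp = params.drive_gain * ramp_value * abs(h) * params.obs_gain * r0
    psi = cmath.phase(h)
    beta = math.radians(params.drive_angle_beta_deg)
    if params.obs_component == "im":
        # observing Im(z): the oscillator phase seen in the LFP lags arg z by 90°
        psi += math.pi / 2

    d_r = amp * math.cos(psi + beta) / (4.0 * params.mu)
    d_omega = amp * math.sin(psi + beta) / (2.0 * r0) - 2.0 * params.shear * r0 * d_r
    df_hz = d_omega / (2 * math.pi)

    # The LFP tone amplitude is not the limit-cycle radius alone: the
    # counter-rotating half of the feedback force drives a 2*omega
    # perturbation of the rotating-frame state whose mixing back into
    # the carrier adds a forced component at the tone frequency,
    #   dA_forced = Re[(A/4) e^{-i(beta-psi)} (1/(2mu+2iw) + 1/(2iw))],
    # a rotation of the observed power curve by ~atan(mu/omega)
    # relative to the radius response (zero-shear linearization).
    w = params.omega0
    f2_conj = (amp / 2.0) * cmath.exp(-1j * (beta - psi))
    c_minus = 0.5 * f2_conj * (1.0 / (2 * params.mu + 2j * w) + 1.0 / (2j * w))
    d_amp_obs = d_r + c_minus.real

    dp_frac = 2.0 * d_amp_obs / r0
    return {
        "df_hz": df_hz,
        "dp_frac": dp_frac,
        "dr_frac": d_r / r0,
        "f_ratio": 1.0 + df_hz / f0,
        "p_ratio": 1.0 + dp_frac,
        "p_ratio_state": 1.0 + 2.0 * d_r / r0,
        "psi_eff_deg": float(wrap_deg(math.degrees(psi))),
        "force_amp": amp,
    }


def analytic_prc(params: StuartLandauParams, phases_deg, normalized: bool = True,
                 kick_amplitude: float = 1.0, kick_duration_ms: float = 1.0):
    """Closed-form phase response of the Stuart–Landau oscillator.

    A brief kick of the drive (impulse area ``drive_gain * amplitude *
    duration``) along e^{i*beta} delivered at trough-convention phase
    theta shifts the asymptotic phase by

        dtheta = (area / R0) * sin(theta - beta)   [radians]

    (zero-shear radial-isochron case; phase advance positive).
    With ``normalized=True`` the curve is degrees of shift per unit
    (amplitude x ms), matching :func:`gammaclamp.prc.measure_prc`.
    """
    import numpy as np

    if params.shear != 0.0:
        raise NotImplementedError("closed-form PRC implemented for shear = 0")
    theta = np.deg2rad(np.asarray(phases_deg, dtype=float))
    beta = math.radians(params.drive_angle_beta_deg)
    area = params.drive_gain * kick_amplitude * (kick_duration_ms * 1e-3)
    shift_rad = (area / params.limit_cycle_radius) * np.sin(theta - beta)
    shift_deg = np.rad2deg(shift_rad)
    if normalized:
        shift_deg = shift_deg / (kick_amplitude * kick_duration_ms)
    return shift_deg
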