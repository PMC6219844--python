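"""Synthetic gamma-oscillation generators ("slices in silico").

Two plants are provided, both advanced sample-by-sample on the 10 kHz
control-loop grid so a feedback controller can be coupled without
interpolation:

* :class:`StuartLandauPlant` — the normal form of a supercritical Hopf
  bifurcation, ``dz/dt = (mu + i*omega0) z - (1 + i*shear)|z|^2 z +
  drive_gain * drive(t) * exp(i*beta) + noise``.  It is the minimal
  model of a noisy limit-cycle oscillation and has closed-form
  amplitude (``sqrt(mu)``), frequency (``omega0/2pi`` minus a shear
  correction) and phase response, which the test-suite uses as an
  analytic oracle.
* :class:`EIMassPlant` — a Wilson–Cowan style excitatory–inhibitory
  mass model (PING-like) that produces a 30–60 Hz field potential with
  a non-sinusoidal waveform and cycle-to-cycle jitter once the
  excitatory drive crosses the oscillation threshold, sparse
  trough-locked pyramidal spiking, and voltage-clamp style membrane
  currents dominated by phasic inhibition.

Both plants observe their state through a measurement stage (causal
1–200 Hz band-pass plus optional white noise) that emulates the
recording chain between the slice and the feedback controller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import (
    DEFAULT_DT,
    RampProtocol,
    SimRun,
    SpikeTrain,
    TimeSeries,
    child_rng,
)

__all__ = [
    "StuartLandauParams",
    "EIMassParams",
    "MeasurementModel",
    "StuartLandauPlant",
    "EIMassPlant",
    "make_ramp",
    "simulate_stuart_landau",
    "simulate_ei_mass",
    "generate_phase_locked_spikes",
    "run_open_loop",
]

# fixed per-component stream offsets under the master seed
STREAM_PLANT = 1
STREAM_SPIKES = 2
STREAM_MEASUREMENT = 3


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class StuartLandauParams:
    """Hopf normal-form oscillator parameters.

    ``mu`` (1/s) is the bifurcation parameter: for ``mu > 0`` the
    deterministic system has a limit cycle of radius ``sqrt(mu)``.
    ``drive_angle_beta`` sets the direction in the state plane along
    which the optogenetic drive acts; the default +90° places the
    drive along the hidden variable in quadrature with the observed
    LFP.  ``obs_gain`` (mV per state unit) maps the observed
    projection of z onto the recorded field potential.
    """

    mu: float = 100.0
    omega0: float = 2 * math.pi * 40.0
    shear: float = 0.0
    drive_gain: float = 0.0
    drive_angle_beta_deg: float = 90.0
    noise_sigma: float = 0.0
    obs_gain: float = 0.03
    obs_component: str = "re"  # 're' | 'im'
    z0: complex | None = None
    #: the plant represents the network *at* its oscillating working
    #: point (the slow ramp is absorbed into mu), so only the fast
    #: component of the drive couples; None disables the high-pass.
    drive_hp_hz: float | None = 1.0

    def __post_init__(self):
        if not self.omega0 > 0:
            raise ValueError("omega0 must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.obs_component not in ("re", "im"):
            raise ValueError("obs_component must be 're' or 'im'")

    @property
    def limit_cycle_radius(self) -> float:
        return math.sqrt(self.mu) if self.mu > 0 else 0.0

    @property
    def limit_cycle_freq_hz(self) -> float:
        """Deterministic cycle frequency: omega0 − shear·mu (rad/s) over 2π."""
        return (self.omega0 - self.shear * self.mu) / (2 * math.pi)


@dataclass
class EIMassParams:
    """Excitatory–inhibitory mass model parameters.

    Rates E, I are dimensionless in [0, 1].  The defaults are tuned so
    that with zero drive the system sits at a fixed point and a
    supra-threshold ramp drive evokes a supercritical (graded,
    quasi-sinusoidal near onset) limit cycle in the low-gamma band,
    with phasic inhibition dominating the synaptic currents of a held
    cell (`i_inh` amplitude > `i_exc` amplitude at baseline).

    Pyramidal spiking is an inhomogeneous Poisson process whose
    intensity follows the *fluctuation* of E about a slow homeostatic
    baseline, plus the direct opsin photocurrent: gamma and the clamp
    redistribute spikes within the cycle while the time-averaged rate
    stays at ``spike_rate_hz`` (sparse, near-trough firing whose
    synchrony — not rate — tracks oscillation power).
    """

    tau_e: float = 0.0033      # s
    tau_i: float = 0.0066      # s
    w_ee: float = 16.0
    w_ei: float = 12.0
    w_ie: float = 15.0
    w_ii: float = 3.0
    gain_e: float = 0.7        # sigmoid slope (E population)
    theta_e: float = 4.0       # sigmoid threshold
    gain_i: float = 1.0
    theta_i: float = 3.7
    drive_gain: float = 2.7    # external drive units -> E input
    tau_syn_e: float = 0.001   # s, synaptic filter for excitatory conductance
    tau_syn_i: float = 0.002   # s, synaptic filter for inhibitory conductance
    ge_gain: float = 1.2       # nS per unit sE (synaptic, onto the held cell)
    gi_gain: float = 4.0       # nS per unit sI
    g_opsin: float = 1.5       # nS per unit opsin drive (direct photocurrent)
    lfp_mix_e: float = 0.70    # LFP weight of excitatory synaptic signal
    lfp_mix_i: float = 0.30    # LFP weight of inhibitory synaptic signal
    lfp_gain: float = 3.0      # mV per unit mixed oscillation
    harmonic_amp: float = 0.8  # quadratic distortion -> non-sinusoidal waveform
    noise_sigma: float = 0.15  # OU noise amplitude on the E drive
    noise_tau: float = 0.005   # s
    spike_rate_hz: float = 3.0      # homeostatic mean rate per cell
    e_mod_scale: float = 0.55       # E fluctuation giving 100% intensity modulation
    opsin_spike_gain: float = 1.5   # intensity modulation per unit drive fluctuation
    homeo_tau: float = 0.3          # s, slow baseline for E and drive fluctuations
    n_cells: int = 12
    driving_force_mv: float = 70.0
    holding_exc_mv: float = -70.0
    holding_inh_mv: float = 0.0

    def __post_init__(self):
        for name in ("tau_e", "tau_i", "tau_syn_e", "tau_syn_i", "noise_tau"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MeasurementModel:
    """Recording chain between plant and controller.

    A causal band-pass (first-order high-pass at ``hp_hz`` and low-pass
    at ``lp_hz``, emulating the 1–200 Hz acquisition filter) plus
    additive white measurement noise applied to the raw LFP before it
    is recorded or fed back.
    """

    hp_hz: float = 1.0
    lp_hz: float = 200.0
    noise_mv: float = 0.0
    enabled: bool = True

    def transfer(self, f_hz: float) -> complex:
        """Continuous-time transfer function at frequency f (Hz)."""
        if not self.enabled:
            return 1.0 + 0.0j
        w = 2 * math.pi * f_hz
        t_hp = 1.0 / (2 * math.pi * self.hp_hz)
        t_lp = 1.0 / (2 * math.pi * self.lp_hz)
        h_hp = (1j * w * t_hp) / (1 + 1j * w * t_hp)
        h_lp = 1.0 / (1 + 1j * w * t_lp)
        return h_hp * h_lp


class _MeasurementState:
    """Per-run causal filter state for a MeasurementModel."""

    def __init__(self, model: MeasurementModel, dt: float, n: int, rng: np.random.Generator):
        self.model = model
        self.a_hp = 1.0 - math.exp(-dt * 2 * math.pi * model.hp_hz)
        self.a_lp = 1.0 - math.exp(-dt * 2 * math.pi * model.lp_hz)
        self.lp_state = 0.0
        self.hp_mean = 0.0
        self.noise = (
            model.noise_mv * rng.standard_normal(n) if model.noise_mv > 0 else None
        )

    def step(self, x: float, i: int) -> float:
        if not self.model.enabled:
            return x + (self.noise[i] if self.noise is not None else 0.0)
        self.hp_mean += self.a_hp * (x - self.hp_mean)
        hp = x - self.hp_mean
        self.lp_state += self.a_lp * (hp - self.lp_state)
        y = self.lp_state
        if self.noise is not None:
            y += self.noise[i]
        return y


# ---------------------------------------------------------------------------
# plants
# ---------------------------------------------------------------------------

class StuartLandauPlant:
    """Step-wise Euler–Maruyama integrator of the Hopf normal form."""

    def __init__(self, params: StuartLandauParams, dt: float = DEFAULT_DT,
                 measurement: MeasurementModel | None = None):
        self.params = params
        self.dt = dt
        self.measurement = measurement if measurement is not None else MeasurementModel()
        self._i = 0

    def reset(self, n_steps: int, seed: int) -> None:
        p = self.params
        self.n = int(n_steps)
        if p.z0 is not None:
            self.z = complex(p.z0)
        elif p.mu > 0:
            self.z = complex(p.limit_cycle_radius, 0.0)
        else:
            self.z = complex(1e-3, 0.0)
        rng = child_rng(seed, STREAM_PLANT)
        if p.noise_sigma > 0:
            self._noise = (p.noise_sigma * math.sqrt(self.dt)) * (
                rng.standard_normal(self.n) + 1j * rng.standard_normal(self.n)
            )
        else:
            self._noise = None
        self._meas = _MeasurementState(
            self.measurement, self.dt, self.n, child_rng(seed, STREAM_MEASUREMENT)
        )
        self._e_beta = complex(
            math.cos(math.radians(p.drive_angle_beta_deg)),
            math.sin(math.radians(p.drive_angle_beta_deg)),
        )
        if p.drive_hp_hz is not None:
            self._drive_hp_a = 1.0 - math.exp(-self.dt * 2 * math.pi * p.drive_hp_hz)
        else:
            self._drive_hp_a = None
        self._drive_mean = 0.0
        self.z_re = np.empty(self.n)
        self.z_im = np.empty(self.n)
        self.lfp_raw = np.empty(self.n)
        self.lfp = np.empty(self.n)
        self._i = 0

    def _f(self, z: complex, drive: float) -> complex:
        p = self.params
        az2 = z.real * z.real + z.imag * z.imag
        return (complex(p.mu, p.omega0) * z
                - complex(1.0, p.shear) * az2 * z
                + p.drive_gain * drive * self._e_beta)

    def step(self, drive: float) -> float:
        # Heun (RK2) step for the drift; additive diffusion increment.
        # A first-order step at the fixed 10 kHz grid biases the cycle
        # radius by ~(omega0*dt)^2 — far above the closed-form checks.
        p, dt = self.params, self.dt
        if self._drive_hp_a is not None:
            self._drive_mean += self._drive_hp_a * (drive - self._drive_mean)
            drive = drive - self._drive_mean
        z = self.z
        f1 = self._f(z, drive)
        f2 = self._f(z + dt * f1, drive)
        z = z + (0.5 * dt) * (f1 + f2)
        if self._noise is not None:
            z = z + self._noise[self._i]
        if not (abs(z.real) < 1e9 and abs(z.imag) < 1e9):
            raise FloatingPointError(
                "Stuart-Landau state diverged (non-finite/huge); "
                f"check dt={dt} against mu={p.mu}, omega0={p.omega0}"
            )
        self.z = z
        i = self._i
        self.z_re[i] = z.real
        self.z_im[i] = z.imag
        raw = p.obs_gain * (z.real if p.obs_component == "re" else z.imag)
        self.lfp_raw[i] = raw
        y = self._meas.step(raw, i)
        self.lfp[i] = y
        self._i = i + 1
        return y

    def extras(self) -> dict:
        return {"z_re": self.z_re, "z_im": self.z_im, "lfp_raw": self.lfp_raw}

    def spike_trains(self) -> list[SpikeTrain]:
        return []

    def finalize_meta(self) -> dict:
        return {"plant": "stuart_landau"}


class EIMassPlant:
    """Wilson–Cowan style E–I mass model with synaptic observables."""

    def __init__(self, params: EIMassParams, dt: float = DEFAULT_DT,
                 measurement: MeasurementModel | None = None):
        self.params = params
        self.dt = dt
        self.measurement = measurement if measurement is not None else MeasurementModel()

    @staticmethod
    def _sigmoid(x: float, gain: float, theta: float) -> float:
        return 1.0 / (1.0 + math.exp(-gain * (x - theta)))

    def reset(self, n_steps: int, seed: int) -> None:
        p = self.params
        self.n = int(n_steps)
        self.E = 0.05
        self.I = 0.05
        self.sE = 0.05
        self.sI = 0.05
        self.ou = 0.0
        self.v_slow = 0.0
        self._a_slow = 1.0 - math.exp(-self.dt / 0.2)  # 200 ms baseline tracker
        self.e_slow = self.E
        self.drive_slow = 0.0
        self._a_homeo = 1.0 - math.exp(-self.dt / p.homeo_tau)
        rng = child_rng(seed, STREAM_PLANT)
        # pre-drawn OU increments and per-cell spike uniforms
        self._ou_decay = math.exp(-self.dt / p.noise_tau)
        ou_scale = p.noise_sigma * math.sqrt(1.0 - self._ou_decay ** 2)
        self._ou_noise = ou_scale * rng.standard_normal(self.n) if p.noise_sigma > 0 else None
        srng = child_rng(seed, STREAM_SPIKES)
        self._spike_u = srng.random((p.n_cells, self.n))
        self._meas = _MeasurementState(
            self.measurement, self.dt, self.n, child_rng(seed, STREAM_MEASUREMENT)
        )
        self.e_rate = np.empty(self.n)
        self.i_rate = np.empty(self.n)
        self.g_e = np.empty(self.n)
        self.g_i = np.empty(self.n)
        self.i_exc = np.empty(self.n)
        self.i_inh = np.empty(self.n)
        self.lfp_raw = np.empty(self.n)
        self.lfp = np.empty(self.n)
        self._spikes: list[list[float]] = [[] for _ in range(p.n_cells)]
        self._i = 0

    def step(self, drive: float) -> float:
        p, dt = self.params, self.dt
        i = self._i
        if self._ou_noise is not None:
            self.ou = self._ou_decay * self.ou + self._ou_noise[i]
        x_e = p.w_ee * self.E - p.w_ei * self.I + p.drive_gain * drive + self.ou
        x_i = p.w_ie * self.E - p.w_ii * self.I
        fE = self._sigmoid(x_e, p.gain_e, p.theta_e)
        fI = self._sigmoid(x_i, p.gain_i, p.theta_i)
        self.E += (dt / p.tau_e) * (-self.E + fE)
        self.I += (dt / p.tau_i) * (-self.I + fI)
        self.sE += (dt / p.tau_syn_e) * (self.E - self.sE)
        self.sI += (dt / p.tau_syn_i) * (self.I - self.sI)

        g_e = p.ge_gain * self.sE + p.g_opsin * max(drive, 0.0)
        g_i = p.gi_gain * self.sI
        self.e_rate[i] = self.E
        self.i_rate[i] = self.I
        self.g_e[i] = g_e
        self.g_i[i] = g_i
        self.i_exc[i] = -g_e * p.driving_force_mv          # inward at −70 mV
        self.i_inh[i] = g_i * p.driving_force_mv           # outward at 0 mV

        v = p.lfp_mix_e * self.sE + p.lfp_mix_i * self.sI
        self.v_slow += self._a_slow * (v - self.v_slow)
        osc = v - self.v_slow
        raw = p.lfp_gain * (-osc + p.harmonic_amp * osc * osc)
        self.lfp_raw[i] = raw
        y = self._meas.step(raw, i)
        self.lfp[i] = y

        # homeostatically normalized Poisson intensity: the E fluctuation
        # and the direct photocurrent redistribute spikes within the
        # cycle; zero-mean modulation leaves the mean rate untouched
        self.e_slow += self._a_homeo * (self.E - self.e_slow)
        self.drive_slow += self._a_homeo * (drive - self.drive_slow)
        mod = (1.0
               + (self.E - self.e_slow) / p.e_mod_scale
               + p.opsin_spike_gain * (drive - self.drive_slow))
        lam_dt = p.spike_rate_hz * dt * mod
        if lam_dt > 0:
            t = i * dt
            urow = self._spike_u[:, i]
            for c in range(p.n_cells):
                if urow[c] < lam_dt:
                    self._spikes[c].append(t)
        self._i = i + 1
        return y

    def extras(self) -> dict:
        return {
            "e_rate": self.e_rate, "i_rate": self.i_rate,
            "g_e": self.g_e, "g_i": self.g_i, "lfp_raw": self.lfp_raw,
        }

    def spike_trains(self) -> list[SpikeTrain]:
        return [
            SpikeTrain(np.asarray(ts), source=f"cell{c}")
            for c, ts in enumerate(self._spikes)
        ]

    def finalize_meta(self) -> dict:
        meta = {"plant": "ei_mass"}
        # flag non-oscillating parameter regimes rather than raising
        n = self._i
        if n > int(1.0 / self.dt):
            seg = self.lfp[n // 2:n]
            f, pxx = sps.welch(seg, fs=1.0 / self.dt, nperseg=min(4096, seg.size))
            band = (f >= 25) & (f <= 90)
            lowband = (f >= 2) & (f < 25)
            peak = pxx[band].max() if band.any() else 0.0
            floor = np.median(pxx[lowband]) if lowband.any() else np.inf
            meta["oscillating"] = bool(peak > 10.0 * floor)
        return meta


# ---------------------------------------------------------------------------
# drives and open-loop simulation
# ---------------------------------------------------------------------------

def make_ramp(protocol: RampProtocol, dt: float = DEFAULT_DT) -> TimeSeries:
    """Linear light-ramp command: zero before onset, peaking at sweep end."""
    n = int(round(protocol.duration_s / dt))
    if n < 1:
        raise ValueError("ramp duration shorter than one sample")
    t = np.arange(n) * dt
    peak_t = (protocol.ramp_plateau_s if protocol.ramp_plateau_s is not None
              else protocol.duration_s)
    span = peak_t - protocol.ramp_start_s
    if span <= 0:
        raise ValueError("ramp_start_s must precede end of sweep")
    vals = protocol.ramp_peak_command * np.clip((t - protocol.ramp_start_s) / span, 0.0, 1.0)
    return TimeSeries(vals, dt, units="V")


def run_open_loop(plant, drive: TimeSeries, seed: int,
                  protocol: RampProtocol | None = None) -> SimRun:
    """Advance a plant through a prescribed drive (no feedback)."""
    if protocol is None:
        protocol = RampProtocol(duration_s=drive.duration, clamp_window=(0.0, 0.0))
    if abs(plant.dt - drive.dt) > 1e-15:
        raise ValueError("plant dt must match drive dt")
    n = drive.n
    plant.reset(n, seed)
    vals = drive.values
    for i in range(n):
        plant.step(vals[i])
    extras = plant.extras()
    run = SimRun(
        lfp=TimeSeries(plant.lfp, drive.dt, "mV"),
        led_command=drive.copy_with(drive.values.copy()),
        opsin_drive=drive.copy_with(drive.values.copy(), units="a.u."),
        protocol=protocol,
        seed=int(seed),
        spikes=plant.spike_trains(),
        extras=extras,
        meta=plant.finalize_meta(),
    )
    if "g_e" in extras:
        p = plant.params
        run.i_exc_hold = TimeSeries(plant.i_exc, drive.dt, "pA")
        run.i_inh_hold = TimeSeries(plant.i_inh, drive.dt, "pA")
        run.meta["holding_exc_mv"] = p.holding_exc_mv
        run.meta["holding_inh_mv"] = p.holding_inh_mv
    return run


def simulate_stuart_landau(params: StuartLandauParams, drive: TimeSeries,
                           seed: int, measurement: MeasurementModel | None = None) -> SimRun:
    """Open-loop Hopf normal-form run under a prescribed drive."""
    plant = StuartLandauPlant(params, dt=drive.dt, measurement=measurement)
    return run_open_loop(plant, drive, seed)


def simulate_ei_mass(params: EIMassParams, drive: TimeSeries,
                     seed: int, measurement: MeasurementModel | None = None) -> SimRun:
    """Open-loop E–I mass-model run under a prescribed drive."""
    plant = EIMassPlant(params, dt=drive.dt, measurement=measurement)
    return run_open_loop(plant, drive, seed)


def generate_phase_locked_spikes(phase_track: TimeSeries, mean_rate: float,
                                 kappa: float, pref_phase_deg: float,
                                 duration: float | None = None,
                                 seed: int = 0) -> SpikeTrain:
    """Inhomogeneous Poisson spikes with von Mises phase modulation.

    The intensity is ``mean_rate * exp(kappa cos(phase - pref)) /
    I0(kappa)``, so the time-averaged rate equals ``mean_rate``
    whenever the phase track sweeps the circle uniformly — the
    modulation depth redistributes spikes within the cycle without
    changing how many there are.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if mean_rate < 0:
        raise ValueError("mean_rate must be non-negative")
    phases = np.deg2rad(phase_track.values)
    n = phases.size
    if duration is not None:
        n = min(n, int(round(duration / phase_track.dt)))
        phases = phases[:n]
    from scipy.special import i0
    lam = mean_rate * np.exp(kappa * np.cos(phases - math.radians(pref_phase_deg))) / i0(kappa)
    p = lam * phase_track.dt
    if p.max(initial=0.0) > 0.5:
        raise ValueError("rate too high for the sampling grid (lambda*dt > 0.5)")
    rng = child_rng(seed, STREAM_SPIKES)
    hits = np.nonzero(rng.random(n) < p)[0]
    times = phase_track.t0 + hits * phase_track.dt
    return SpikeTrain(times, source="vonmises")
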