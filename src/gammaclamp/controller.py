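"""Discrete-time analogue feedback controller ("gamma clamp").

The control law multiplies a slow excitatory ramp command by
``(1 + k1*LFP + k2*dLFP/dt)`` inside a clamp window, with the
derivative computed as successive sample differences averaged over a
trailing 2 ms boxcar, exactly as a hardware loop running at 10 kHz
would.  The commanded light passes through a threshold-linear driver
(no negative light) and a first-order opsin activation/deactivation
stage with asymmetric time constants before it reaches the plant.

The closed loop is strictly causal: the controller output at step n
uses plant output up to step n−1 (one loop-sample feedback latency,
0.1 ms at the default rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DEFAULT_DT, RampProtocol, SimRun, TimeSeries
from .synth import make_ramp

__all__ = [
    "ControllerConfig",
    "OpsinModel",
    "lfp_derivative",
    "command",
    "opsin_filter",
    "run_closed_loop",
]


@dataclass
class ControllerConfig:
    """Feedback-law settings.

    ``k1`` is in 1/mV, ``k2`` in ms/mV, so with the LFP in mV and its
    derivative in mV/ms both feedback terms are dimensionless
    multipliers on the ramp.  ``deriv_avg_ms`` must be an integer
    multiple of the loop period.  ``clamp_window`` of ``None`` defers
    to the ramp protocol's window.
    """

    k1: float = 0.0
    k2: float = 0.0
    deriv_avg_ms: float = 2.0
    loop_rate_hz: float = 10_000.0
    clamp_window: tuple[float, float] | None = None
    driver_threshold: float = 0.0
    feedback_delay_steps: int = 1

    def __post_init__(self):
        dt_ms = 1000.0 / self.loop_rate_hz
        ratio = self.deriv_avg_ms / dt_ms
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 2:
            raise ValueError(
                "deriv_avg_ms must be an integer multiple (>= 2) of the loop period"
            )
        if self.feedback_delay_steps < 1:
            raise ValueError("feedback latency is at least one loop sample")

    @property
    def deriv_window_samples(self) -> int:
        return int(round(self.deriv_avg_ms * self.loop_rate_hz / 1000.0))


@dataclass
class OpsinModel:
    """First-order opsin kinetics: low-pass with asymmetric on/off taus."""

    tau_on_ms: float = 6.0
    tau_off_ms: float = 12.0
    gain: float = 1.0

    def __post_init__(self):
        if not (self.tau_on_ms > 0 and self.tau_off_ms > 0):
            raise ValueError("opsin time constants must be positive")

    def alphas(self, dt: float) -> tuple[float, float]:
        return (
            1.0 - math.exp(-dt * 1000.0 / self.tau_on_ms),
            1.0 - math.exp(-dt * 1000.0 / self.tau_off_ms),
        )

    def transfer(self, f_hz: float) -> complex:
        """Small-signal transfer (symmetric-tau approximation)."""
        tau_s = 0.5 * (self.tau_on_ms + self.tau_off_ms) * 1e-3
        return self.gain / (1.0 + 1j * 2 * math.pi * f_hz * tau_s)


def lfp_derivative(lfp: TimeSeries, deriv_avg_ms: float = 2.0) -> TimeSeries:
    """Causal LFP slope in mV/ms: first difference, trailing boxcar average.

    Output sample t uses samples at or before t only; the first window
    fills gradually (partial averages), matching the streaming loop.
    """
    dt_ms = lfp.dt * 1000.0
    w = int(round(deriv_avg_ms / dt_ms))
    if w < 2:
        raise ValueError("derivative averaging window must span at least 2 samples")
    diffs = np.empty(lfp.n)
    diffs[0] = 0.0
    diffs[1:] = np.diff(lfp.values) / dt_ms
    csum = np.concatenate(([0.0], np.cumsum(diffs)))
    out = np.empty(lfp.n)
    idx = np.arange(lfp.n)
    lo = np.maximum(idx - w + 1, 0)
    out = (csum[idx + 1] - csum[lo]) / (idx - lo + 1)
    return lfp.copy_with(out, units="mV/ms")


def command(ramp_value: float, lfp_value: float, dlfp_value: float,
            cfg: ControllerConfig, t: float,
            clamp_window: tuple[float, float] | None = None) -> float:
    """Threshold-linear LED command at time t (pure function).

    Inside the clamp window the ramp is multiplied by
    ``1 + k1*lfp + k2*dlfp``; outside, the factor is identically 1.
    The driver clips at ``driver_threshold`` (no negative light).
    """
    window = cfg.clamp_window if cfg.clamp_window is not None else clamp_window
    in_window = window is not None and window[0] <= t < window[1]
    factor = 1.0 + cfg.k1 * lfp_value + cfg.k2 * dlfp_value if in_window else 1.0
    return max(cfg.driver_threshold, ramp_value * factor)


def opsin_filter(cmd: TimeSeries, model: OpsinModel) -> TimeSeries:
    """Asymmetric first-order opsin activation applied to a command trace."""
    a_on, a_off = model.alphas(cmd.dt)
    out = np.empty(cmd.n)
    s = 0.0
    vals = cmd.values
    g = model.gain
    for i in range(cmd.n):
        target = g * vals[i]
        a = a_on if target > s else a_off
        s += a * (target - s)
        out[i] = s
    return cmd.copy_with(out, units="a.u.")


def run_closed_loop(plant, cfg: ControllerConfig, opsin: OpsinModel,
                    protocol: RampProtocol, seed: int) -> SimRun:
    """Co-simulate plant and controller on a shared sample grid.

    Each step: read the plant LFP of the *previous* step, update the
    trailing-boxcar derivative, form the (possibly clamped) command,
    clip at the driver threshold, advance the opsin state, and feed the
    resulting drive to the plant.
    """
    dt = plant.dt
    if abs(1.0 / dt - cfg.loop_rate_hz) > 1e-6 * cfg.loop_rate_hz:
        raise ValueError("controller loop rate must match plant dt")
    ramp = make_ramp(protocol, dt)
    n = ramp.n
    window = cfg.clamp_window if cfg.clamp_window is not None else protocol.clamp_window
    w0, w1 = window
    has_window = w1 > w0
    wlen = cfg.deriv_window_samples
    dt_ms = dt * 1000.0
    a_on, a_off = opsin.alphas(dt)
    g = opsin.gain
    k1, k2, thr = cfg.k1, cfg.k2, cfg.driver_threshold
    delay = cfg.feedback_delay_steps

    plant.reset(n, seed)
    led = np.empty(n)
    drive = np.empty(n)
    lfp_hist = plant.lfp  # plant records measured LFP here as it steps
    diffs = np.zeros(n)
    dsum = 0.0
    s = 0.0
    ramp_vals = ramp.values
    for i in range(n):
        j = i - delay
        lfp_prev = lfp_hist[j] if j >= 0 else 0.0
        # trailing boxcar of first differences, up to sample j
        if j >= 1:
            d = (lfp_hist[j] - lfp_hist[j - 1]) / dt_ms
            diffs[j] = d
            dsum += d
            if j - wlen >= 1:
                dsum -= diffs[j - wlen]
            dbar = dsum / min(j, wlen)
        else:
            dbar = 0.0
        t = i * dt
        if has_window and w0 <= t < w1:
            factor = 1.0 + k1 * lfp_prev + k2 * dbar
        else:
            factor = 1.0
        cmd = ramp_vals[i] * factor
        if cmd < thr:
            cmd = thr
        led[i] = cmd
        target = g * cmd
        a = a_on if target > s else a_off
        s += a * (target - s)
        drive[i] = s
        plant.step(s)

    run = SimRun(
        lfp=TimeSeries(plant.lfp, dt, "mV"),
        led_command=TimeSeries(led, dt, "V"),
        opsin_drive=TimeSeries(drive, dt, "a.u."),
        protocol=protocol,
        seed=int(seed),
        spikes=plant.spike_trains(),
        extras=plant.extras(),
        meta=plant.finalize_meta(),
    )
    run.meta.update({
        "k1": cfg.k1, "k2": cfg.k2,
        "clamp_window": list(window),
        "opsin_tau_on_ms": opsin.tau_on_ms, "opsin_tau_off_ms": opsin.tau_off_ms,
    })
    if hasattr(plant, "i_exc"):
        p = plant.params
        run.i_exc_hold = TimeSeries(plant.i_exc, dt, "pA")
        run.i_inh_hold = TimeSeries(plant.i_inh, dt, "pA")
        run.meta["holding_exc_mv"] = p.holding_exc_mv
        run.meta["holding_inh_mv"] = p.holding_inh_mv
    return run
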