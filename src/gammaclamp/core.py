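"""Core containers shared across the simulation and analysis layers.

Conventions used throughout the package:

* Signals are uniformly sampled :class:`TimeSeries` with an explicit
  sampling interval ``dt`` (seconds; default 1e-4, i.e. a 10 kHz loop
  rate) and a units string (``mV`` for the field potential, ``V`` for
  the LED command, ``pA`` for membrane currents, ``nS`` for
  conductances, ``a.u.`` for the opsin drive).
* Oscillation phase is measured in degrees with the LFP *trough* at 0°,
  increasing through the cycle, range [0°, 360°).  A "phase advance" is
  a shift toward smaller phase.
* Inward membrane currents are negative, outward currents positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "SpikeTrain",
    "PhaseVector",
    "RampProtocol",
    "SimRun",
    "CycleSet",
    "CycleAverage",
    "wrap_deg",
    "circdiff_deg",
    "child_rng",
]

#: default sampling interval (s) — the 10 kHz acquisition/control loop
DEFAULT_DT = 1e-4


def wrap_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angle (degrees) into [0, 360)."""
    a = np.mod(angle, 360.0)
    # guard against np.mod(-tiny, 360) == 360.0 under rounding
    return np.where(a >= 360.0, 0.0, a) if np.ndim(a) else (0.0 if a >= 360.0 else a)


def circdiff_deg(a, b):
    """Signed circular difference a − b in degrees, in (−180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    d = np.where(d > 180.0, d - 360.0, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Derive an independent random stream from a master seed.

    Every stochastic component (plant noise, spike draws, measurement
    noise, ...) pulls its own generator via a fixed stream offset, so a
    single master seed reproduces a whole experiment bit-exactly while
    components stay statistically independent.
    """
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((int(seed), int(stream)))))


@dataclass
class TimeSeries:
    """A uniformly sampled signal with units.

    Parameters
    ----------
    values : array-like
        Sample values.
    dt : float
        Sampling interval in seconds (> 0).
    units : str
        Physical units of ``values`` (non-empty).
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    dt: float = DEFAULT_DT
    units: str = "a.u."
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("TimeSeries requires a 1-d array with at least one sample")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.units:
            raise ValueError("units string must be non-empty")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (seconds)."""
        i = int(round((t - self.t0) / self.dt))
        return min(max(i, 0), self.n - 1)

    def slice(self, t_start: float, t_stop: float) -> "TimeSeries":
        """Sub-series covering [t_start, t_stop) (clipped to the span)."""
        i0 = self.index_at(t_start)
        i1 = self.index_at(t_stop)
        if i1 <= i0:
            raise ValueError("empty time slice")
        return TimeSeries(self.values[i0:i1], self.dt, self.units, self.t0 + i0 * self.dt)

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "TimeSeries":
        return TimeSeries(np.asarray(values, dtype=float), self.dt, units or self.units, self.t0)


@dataclass
class SpikeTrain:
    """Sorted spike times (seconds) from one cell."""

    spike_times: np.ndarray
    source: str = "cell0"

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.spike_times.size

    def rate(self, duration: float) -> float:
        return self.n / duration if duration > 0 else np.nan


@dataclass
class PhaseVector:
    """Magnitude plus angle (degrees, trough = 0°).

    ``magnitude`` is the mean resultant length R in [0, 1] for
    unit-weight spike-phase averages, or a current amplitude in pA for
    cycle-averaged phasic currents.  ``angle`` is reported in [0, 360);
    it is flagged undefined when the magnitude is (numerically) zero.
    """

    magnitude: float
    angle_deg: float
    angle_defined: bool = True

    def __post_init__(self):
        self.magnitude = float(self.magnitude)
        self.angle_deg = float(wrap_deg(self.angle_deg)) if self.angle_defined else float("nan")

    def cartesian(self) -> tuple[float, float]:
        if not self.angle_defined:
            return (0.0, 0.0)
        a = np.deg2rad(self.angle_deg)
        return (self.magnitude * np.cos(a), self.magnitude * np.sin(a))

    @classmethod
    def from_cartesian(cls, x: float, y: float, tol: float = 1e-12) -> "PhaseVector":
        mag = float(np.hypot(x, y))
        if mag <= tol:
            return cls(0.0, 0.0, angle_defined=False)
        return cls(mag, np.rad2deg(np.arctan2(y, x)))


@dataclass
class RampProtocol:
    """Timing of the light ramp and of the closed-loop clamp window.

    The ramp rises linearly from zero (at ``ramp_start_s``) to
    ``ramp_peak_command`` at the end of the sweep; the clamp multiplies
    the command only inside ``clamp_window``.  Ramps last 8 s by
    default, with the clamp engaged for a 2 s mid-ramp window.
    """

    duration_s: float = 8.0
    ramp_start_s: float = 0.0
    ramp_peak_command: float = 1.0
    clamp_window: tuple[float, float] = (5.0, 7.0)
    k1: float = 0.0  # per mV
    k2: float = 0.0  # ms per mV
    #: time at which the ramp saturates at its peak; None = end of sweep.
    #: A plateau before the clamp window keeps the baseline oscillation
    #: stationary across the window and its flanks.
    ramp_plateau_s: float | None = None

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError("ramp duration must be positive")
        if self.ramp_plateau_s is not None and not (
                self.ramp_start_s < self.ramp_plateau_s <= self.duration_s):
            raise ValueError("ramp_plateau_s must lie inside the sweep")
        lo, hi = self.clamp_window
        if not (0.0 <= lo <= hi <= self.duration_s):
            raise ValueError("clamp_window must lie inside [0, duration_s]")


@dataclass
class SimRun:
    """Bundle of co-simulated traces plus protocol metadata and seed.

    All traces share the sampling grid.  ``extras`` holds
    plant-specific internals (population rates, conductances, the raw
    pre-measurement LFP, ...) keyed by name.
    """

    lfp: TimeSeries
    led_command: TimeSeries
    opsin_drive: TimeSeries
    protocol: RampProtocol
    seed: int
    spikes: list[SpikeTrain] = field(default_factory=list)
    i_exc_hold: TimeSeries | None = None
    i_inh_hold: TimeSeries | None = None
    extras: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for ts in self._all_traces():
            if abs(ts.dt - self.lfp.dt) > 1e-15 or ts.n != self.lfp.n:
                raise ValueError("all SimRun traces must share dt and span")

    def _all_traces(self):
        out = [self.lfp, self.led_command, self.opsin_drive]
        if self.i_exc_hold is not None:
            out.append(self.i_exc_hold)
        if self.i_inh_hold is not None:
            out.append(self.i_inh_hold)
        return out

    @property
    def dt(self) -> float:
        return self.lfp.dt


@dataclass
class CycleSet:
    """Detected LFP troughs with per-cycle acceptance flags.

    Cycle *i* spans trough ``trough_indices[i]`` to
    ``trough_indices[i+1]``; it is accepted when its period deviates
    from the modal period by at most ``rejection_tolerance`` (a
    fraction, boundary inclusive).
    """

    trough_indices: np.ndarray
    modal_period_s: float
    accepted: np.ndarray
    rejection_tolerance: float = 0.20
    dt: float = DEFAULT_DT

    def __post_init__(self):
        self.trough_indices = np.asarray(self.trough_indices, dtype=int)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if self.trough_indices.size > 1 and not np.all(np.diff(self.trough_indices) > 0):
            raise ValueError("trough indices must be strictly increasing")
        if self.accepted.size != max(self.trough_indices.size - 1, 0):
            raise ValueError("need one acceptance flag per cycle (n_troughs - 1)")

    @property
    def n_cycles(self) -> int:
        return self.accepted.size

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    def periods_s(self) -> np.ndarray:
        return np.diff(self.trough_indices) * self.dt


@dataclass
class CycleAverage:
    """Cycle-averaged signal on a uniform phase grid (trough = 0°)."""

    phase_bins_deg: np.ndarray
    mean_current: np.ndarray
    n_cycles: int
    units: str = "pA"
    holding_mv: float | None = None

    def __post_init__(self):
        self.phase_bins_deg = np.asarray(self.phase_bins_deg, dtype=float)
        self.mean_current = np.asarray(self.mean_current, dtype=float)
        if self.phase_bins_deg.shape != self.mean_current.shape:
            raise ValueError("phase grid and values must have equal length")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.phase_bins_deg.size
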