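"""Experiment orchestration: configured clamp sweeps and run I/O.

A sweep steps through a grid of feedback settings — explicit (k1, k2)
pairs, or target feedback phases converted to (k1, k2) with the
pure-tone mixing relation — running the closed loop once per grid
point and collecting the spectral ratios, the LED–LFP phase, spike
statistics, and the net imposed excitatory current vector into one
tidy table.  Runs serialize losslessly to HDF5 (one group per trace)
and lossily to long-format CSV.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .controller import ControllerConfig, OpsinModel, run_closed_loop
from .core import PhaseVector, RampProtocol, SimRun, SpikeTrain, TimeSeries
from .cycles import (accept_cycles, current_vector, cycle_average,
                     delta_vector, detect_troughs, phasic_component)
from .spectral import clamp_ratios, led_lfp_phase
from .spikes import circular_mean, spike_phase_table
from .synth import (EIMassParams, EIMassPlant, MeasurementModel,
                    StuartLandauParams, StuartLandauPlant)
from .theory import phase_to_gains

__all__ = [
    "ExperimentConfig",
    "build_plant",
    "run_sweep",
    "epoch_current_vector",
    "spike_stats_for_window",
    "write_run",
    "read_run",
    "export_csv",
    "import_csv",
]


@dataclass
class ExperimentConfig:
    """Fully serializable description of a clamp sweep.

    A sweep is reproducible from the config plus its master seed
    alone.  The grid is either ``gains`` (list of [k1, k2]) or
    ``phases_deg`` plus ``gain_per_mv``/``f0_hz`` for the pure-tone
    conversion.
    """

    plant: str = "sl"  # 'sl' | 'ei'
    plant_params: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    opsin: dict = field(default_factory=dict)
    measurement: dict = field(default_factory=dict)
    controller: dict = field(default_factory=dict)  # shared settings
    gains: list | None = None
    phases_deg: list | None = None
    gain_per_mv: float = 0.6
    f0_hz: float = 40.0
    seed: int = 0
    analysis: dict = field(default_factory=dict)

    def grid(self) -> list[tuple[float, float]]:
        if self.gains is not None:
            return [tuple(g) for g in self.gains]
        if self.phases_deg is not None:
            return [phase_to_gains(p, self.gain_per_mv, self.f0_hz)
                    for p in self.phases_deg]
        return []

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_plant(cfg: ExperimentConfig):
    meas = MeasurementModel(**cfg.measurement)
    if cfg.plant == "sl":
        return StuartLandauPlant(StuartLandauParams(**cfg.plant_params),
                                 measurement=meas)
    if cfg.plant == "ei":
        return EIMassPlant(EIMassParams(**cfg.plant_params), measurement=meas)
    raise ValueError(f"unknown plant {cfg.plant!r}")


def spike_stats_for_window(run: SimRun, window: tuple[float, float],
                           band=(20.0, 120.0)) -> dict:
    """Pooled spike-phase statistics inside one time window."""
    times = np.sort(np.concatenate(
        [s.spike_times for s in run.spikes])) if run.spikes else np.array([])
    sel = times[(times >= window[0]) & (times < window[1])]
    out = {"n_spikes": int(sel.size),
           "rate_hz": float(sel.size / ((window[1] - window[0]) * max(len(run.spikes), 1)))}
    if sel.size >= 3:
        tab = spike_phase_table(run.lfp, sel, band=band)
        ok = tab[tab.status == "ok"]
        if len(ok) >= 3:
            pv = circular_mean(ok.phase_deg.values)
            out["R"] = pv.magnitude
            out["mean_phase_deg"] = pv.angle_deg
    return out


def epoch_current_vector(run: SimRun, window: tuple[float, float],
                         which: str = "exc", n_bins: int = 64,
                         band=(20.0, 120.0)) -> PhaseVector:
    """Phasic current phase vector for one epoch of a run.

    Troughs are detected on the LFP restricted to ``window``; the
    matching current trace is cycle-averaged, reduced to its phasic
    component at the recorded holding potential, and summarised as an
    amplitude-weighted phase vector.
    """
    trace = run.i_exc_hold if which == "exc" else run.i_inh_hold
    if trace is None:
        raise ValueError(f"run has no {which} holding-current trace")
    hold = run.meta.get("holding_exc_mv" if which == "exc" else "holding_inh_mv",
                        -70.0 if which == "exc" else 0.0)
    lfp_seg = run.lfp.slice(*window)
    cur_seg = trace.slice(*window)
    troughs = detect_troughs(lfp_seg, band=band)
    cset = accept_cycles(troughs, dt=run.dt)
    avg = cycle_average(cur_seg, cset, n_bins=n_bins, holding_mv=hold)
    return current_vector(phasic_component(avg))


def run_sweep(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the closed loop over the whole grid and aggregate a table.

    Every row carries the requested gains, the realized spectral
    ratios, the LED–LFP phase, spike statistics when the plant spikes,
    and the ΔE vector when holding currents exist.  Failures at a grid
    point are recorded (column ``error``) and the sweep continues.
    Deterministic for a fixed (config, seed).
    """
    protocol = RampProtocol(**cfg.protocol)
    opsin = OpsinModel(**cfg.opsin)
    window = cfg.controller.get("clamp_window", protocol.clamp_window)
    rows = []
    for idx, (k1, k2) in enumerate(cfg.grid()):
        row: dict = {"trial": idx, "k1": k1, "k2": k2,
                     "requested_phase_deg": (cfg.phases_deg[idx]
                                             if cfg.phases_deg is not None else math.nan),
                     "seed": int((cfg.seed * 1009 + idx) % (2 ** 31)),
                     "config_hash": cfg.config_hash(), "error": ""}
        try:
            ctrl = ControllerConfig(k1=k1, k2=k2,
                                    **{k: v for k, v in cfg.controller.items()
                                       if k != "clamp_window"})
            plant = build_plant(cfg)
            run = run_closed_loop(plant, ctrl, opsin, protocol, row["seed"])
            summ = clamp_ratios(run, clamp_window=window,
                                **cfg.analysis.get("clamp_ratios", {}))
            row.update(f_ratio=summ.f_ratio, p_ratio=summ.p_ratio,
                       f_clamped=summ.f_clamped, f_unclamped=summ.f_unclamped,
                       p_clamped=summ.p_clamped, p_unclamped=summ.p_unclamped)
            inner = (window[0] + 0.1, window[1] - 0.1)
            row["led_lfp_phase_deg"] = led_lfp_phase(run.lfp, run.led_command,
                                                     window=inner)
            if run.spikes:
                st = spike_stats_for_window(run, window)
                row.update({f"spike_{k}": v for k, v in st.items()})
            if run.i_exc_hold is not None:
                try:
                    pre = (max(protocol.ramp_start_s, window[0] - 1.5), window[0])
                    v_c = epoch_current_vector(run, window)
                    v_u = epoch_current_vector(run, pre)
                    de = delta_vector(v_c, v_u)
                    row.update(dE_pA=de.magnitude, dE_phase_deg=de.angle_deg,
                               exc_clamped_pA=v_c.magnitude,
                               exc_clamped_phase_deg=v_c.angle_deg)
                except ValueError as exc:
                    row["error"] = f"current-vector: {exc}"
        except Exception as exc:  # recorded failure; sweep continues
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TRACES = ("lfp", "led_command", "opsin_drive", "i_exc_hold", "i_inh_hold")
_REQUIRED = ("lfp", "led_command", "opsin_drive")


def write_run(path, run: SimRun) -> None:
    """Lossless HDF5 serialization (one group per trace)."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in _TRACES:
            ts = getattr(run, name)
            if ts is None:
                continue
            g = f.create_group(name)
            g.create_dataset("values", data=ts.values)
            g.attrs["dt"] = ts.dt
            g.attrs["units"] = ts.units
            g.attrs["t0"] = ts.t0
        sp = f.create_group("spikes")
        for train in run.spikes:
            sp.create_dataset(train.source, data=train.spike_times.astype(np.float64))
        ex = f.create_group("extras")
        for k, v in run.extras.items():
            ex.create_dataset(k, data=np.asarray(v))
        f.attrs["protocol"] = json.dumps(asdict(run.protocol))
        f.attrs["meta"] = json.dumps(run.meta, default=float)
        f.attrs["seed"] = run.seed


def read_run(path) -> SimRun:
    """Read a SimRun written by :func:`write_run`.

    Raises a schema error naming the first missing dataset/attribute.
    """
    import h5py

    kw: dict = {}
    with h5py.File(path, "r") as f:
        for name in _REQUIRED:
            if name not in f:
                raise KeyError(f"schema error: missing trace group '{name}'")
        for name in _TRACES:
            if name not in f:
                kw[name] = None
                continue
            g = f[name]
            if "values" not in g:
                raise KeyError(f"schema error: missing dataset '{name}/values'")
            for attr in ("dt", "units", "t0"):
                if attr not in g.attrs:
                    raise KeyError(f"schema error: missing attr '{name}@{attr}'")
            kw[name] = TimeSeries(g["values"][...], float(g.attrs["dt"]),
                                  str(g.attrs["units"]), float(g.attrs["t0"]))
        spikes = []
        if "spikes" in f:
            import re

            def natural(k):
                return [int(t) if t.isdigit() else t
                        for t in re.split(r"(\d+)", k)]

            for cell in sorted(f["spikes"].keys(), key=natural):
                spikes.append(SpikeTrain(f["spikes"][cell][...], source=cell))
        extras = {}
        if "extras" in f:
            extras = {k: f["extras"][k][...] for k in f["extras"].keys()}
        protocol = RampProtocol(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in json.loads(f.attrs["protocol"]).items()})
        meta = json.loads(f.attrs["meta"])
        seed = int(f.attrs["seed"])
    return SimRun(lfp=kw["lfp"], led_command=kw["led_command"],
                  opsin_drive=kw["opsin_drive"], protocol=protocol, seed=seed,
                  spikes=spikes, i_exc_hold=kw["i_exc_hold"],
                  i_inh_hold=kw["i_inh_hold"], extras=extras, meta=meta)


def export_csv(path, run: SimRun) -> None:
    """Long-format (time, channel, value) CSV export; lossy float text."""
    frames = []
    for name in _TRACES:
        ts = getattr(run, name)
        if ts is None:
            continue
        frames.append(pd.DataFrame({"time_s": ts.times(), "channel": name,
                                    "value": ts.values, "units": ts.units}))
    for train in run.spikes:
        frames.append(pd.DataFrame({"time_s": train.spike_times,
                                    "channel": f"spikes/{train.source}",
                                    "value": 1.0, "units": "event"}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.9g")


def import_csv(path, protocol: RampProtocol | None = None,
               seed: int = 0) -> SimRun:
    """Rebuild a SimRun (traces and spikes only) from an exported CSV."""
    df = pd.read_csv(path)
    kw: dict = {name: None for name in _TRACES}
    spikes = []
    for channel, sub in df.groupby("channel"):
        if str(channel).startswith("spikes/"):
            spikes.append(SpikeTrain(np.sort(sub.time_s.values),
                                     source=str(channel).split("/", 1)[1]))
            continue
        t = sub.time_s.values
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1e-4
        kw[channel] = TimeSeries(sub.value.values, dt,
                                 str(sub.units.iloc[0]), float(t[0]))
    for name in _REQUIRED:
        if kw[name] is None:
            raise KeyError(f"schema error: missing channel '{name}'")
    if protocol is None:
        protocol = RampProtocol(duration_s=kw["lfp"].duration,
                                clamp_window=(0.0, 0.0))
    return SimRun(lfp=kw["lfp"], led_command=kw["led_command"],
                  opsin_drive=kw["opsin_drive"], protocol=protocol,
                  seed=seed, spikes=spikes, i_exc_hold=kw["i_exc_hold"],
                  i_inh_hold=kw["i_inh_hold"],
                  meta={"source": "csv-import (lossy)"})
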