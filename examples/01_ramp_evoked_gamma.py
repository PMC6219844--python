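"""Ramp-evoked gamma in the E-I mass model.

A slow excitatory ramp drives the network across its oscillation
threshold; above it, a 30-60 Hz field potential with cycle-to-cycle
jitter appears, and sparse pyramidal spiking locks near the LFP
trough.
"""

import numpy as np

from gammaclamp import (EIMassParams, RampProtocol, circular_mean,
                        instantaneous_freq_power, make_ramp, simulate_ei_mass,
                        spike_phase_table)

protocol = RampProtocol(duration_s=8.0, ramp_plateau_s=4.0)
run = simulate_ei_mass(EIMassParams(), make_ramp(protocol), seed=3)

freq, power = instantaneous_freq_power(run.lfp)
t = freq.times()
for lo, hi in [(1.0, 2.0), (3.0, 4.0), (5.0, 7.0)]:
    sel = (t >= lo) & (t < hi)
    print(f"t = {lo:.0f}-{hi:.0f} s: freq = {np.nanmean(freq.values[sel]):5.1f} Hz, "
          f"power = {np.nanmean(power.values[sel]):.3f} mV^2")

spikes = np.sort(np.concatenate([s.spike_times for s in run.spikes]))
spikes = spikes[(spikes > 4.5) & (spikes < 7.8)]
table = spike_phase_table(run.lfp, spikes)
pv = circular_mean(table[table.status == "ok"].phase_deg.values)
print(f"\noscillating: {run.meta['oscillating']}")
print(f"{spikes.size} spikes over 3.3 s x {len(run.spikes)} cells "
      f"({spikes.size / 3.3 / len(run.spikes):.1f} Hz/cell)")
print(f"spike phase locking: R = {pv.magnitude:.2f}, "
      f"mean phase = {pv.angle_deg:.0f} deg (trough = 0 deg)")
# Early in the ramp the drive is subthreshold and power stays at the
# noise floor; on the plateau the network sits in the gamma band and
# pyramidal cells fire sparsely, just before the LFP trough.
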