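"""Cycle-averaged membrane currents and the imposed excitation ΔE.

A voltage-clamped cell (at -70 mV for excitation, 0 mV for inhibition)
sees phasic synaptic currents locked to the gamma cycle.  Cycle
averaging between LFP troughs, subtracting the per-cycle minimum, and
taking the amplitude-weighted circular mean turns each epoch into a
phase vector; the clamped-minus-unclamped difference ΔE is the net
excitatory current the clamp imposes.
"""

from gammaclamp import (ControllerConfig, OpsinModel, conductance,
                        delta_vector, ei_orbit, run_closed_loop)
from gammaclamp.cycles import accept_cycles, cycle_average, detect_troughs, phasic_component
from gammaclamp.pipeline import epoch_current_vector
from gammaclamp.studies import EI_F0_HZ, EI_GAIN_PER_MV, ei_study_protocol
from gammaclamp.synth import EIMassParams, EIMassPlant, MeasurementModel
from gammaclamp.theory import phase_to_gains

k1, k2 = phase_to_gains(45.0, EI_GAIN_PER_MV, EI_F0_HZ)
run = run_closed_loop(EIMassPlant(EIMassParams(), measurement=MeasurementModel()),
                      ControllerConfig(k1=k1, k2=k2), OpsinModel(),
                      ei_study_protocol(), seed=2)

v_unclamped = epoch_current_vector(run, (4.0, 5.0), which="exc")
v_clamped = epoch_current_vector(run, (5.0, 7.0), which="exc")
d_e = delta_vector(v_clamped, v_unclamped)
print(f"phasic excitation, unclamped: {v_unclamped.magnitude:5.1f} pA "
      f"@ {v_unclamped.angle_deg:5.1f} deg")
print(f"phasic excitation, clamped:   {v_clamped.magnitude:5.1f} pA "
      f"@ {v_clamped.angle_deg:5.1f} deg")
print(f"imposed current dE:           {d_e.magnitude:5.1f} pA "
      f"@ {d_e.angle_deg:5.1f} deg  (trough = 0 deg)")

# conductance orbit over the cycle (Ohm's law, 70 mV driving force)
lfp = run.lfp.slice(5.0, 7.0)
cycles = accept_cycles(detect_troughs(lfp), dt=run.dt)
g_e = conductance(phasic_component(
    cycle_average(run.i_exc_hold.slice(5.0, 7.0), cycles, holding_mv=-70.0)))
g_i = conductance(phasic_component(
    cycle_average(run.i_inh_hold.slice(5.0, 7.0), cycles, holding_mv=0.0)))
orbit = ei_orbit(g_e, g_i)
print(f"\n{cycles.n_accepted}/{cycles.n_cycles} cycles accepted "
      f"(modal period {1000 * cycles.modal_period_s:.1f} ms)")
print(f"peak conductances: g_e = {g_e.mean_current.max():.2f} nS, "
      f"g_i = {g_i.mean_current.max():.2f} nS")
print(f"E-I orbit direction: {orbit.direction} "
      f"(counter-clockwise = excitation leads inhibition)")
# The clamp imposes its excitatory current on the falling phase of the
# LFP, ahead of the spikes; inhibition follows excitation around the
# cycle, tracing a counter-clockwise loop in the (g_e, g_i) plane.
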