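import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammaclamp.core import RampProtocol, TimeSeries
from gammaclamp.spikes import circular_mean, vonmises_resultant_length
from gammaclamp.synth import (EIMassParams, MeasurementModel,
                              StuartLandauParams, generate_phase_locked_spikes,
                              make_ramp, simulate_ei_mass,
                              simulate_stuart_landau)


def _zero_drive(n=30000):
    return TimeSeries(np.zeros(n), 1e-4, "V")


class TestStuartLandau:
    def test_subcritical_state_decays(self):
        p = StuartLandauParams(mu=-10.0, noise_sigma=0.0, z0=1.0)
        run = simulate_stuart_landau(p, _zero_drive(10000), 1,
                                     MeasurementModel(enabled=False))
        final = abs(run.extras["z_re"][-1] + 1j * run.extras["z_im"][-1])
        assert final < 1e-3

    def test_limit_cycle_amplitude_and_frequency_closed_form(self):
        from gammaclamp.spectral import instantaneous_freq_power
        p = StuartLandauParams(mu=100.0, noise_sigma=0.0)
        run = simulate_stuart_landau(p, _zero_drive(), 1,
                                     MeasurementModel(enabled=False))
        amp = np.abs(run.extras["z_re"][-10000:]
                     + 1j * run.extras["z_im"][-10000:]).mean()
        assert amp == pytest.approx(10.0, rel=1e-3)
        ft, _ = instantaneous_freq_power(run.lfp)
        f = np.nanmean(ft.values[ft.times() > 0.5])
        assert f == pytest.approx(40.0, rel=1e-3)

    def test_shear_shifts_frequency(self):
        from gammaclamp.spectral import instantaneous_freq_power
        p = StuartLandauParams(mu=100.0, shear=0.3, noise_sigma=0.0)
        run = simulate_stuart_landau(p, _zero_drive(), 1,
                                     MeasurementModel(enabled=False))
        ft, _ = instantaneous_freq_power(run.lfp)
        f = np.nanmean(ft.values[ft.times() > 0.5])
        assert f == pytest.approx(p.limit_cycle_freq_hz, rel=1e-3)

    def test_seed_replay_contract(self):
        p = StuartLandauParams(mu=100.0, noise_sigma=2.0)
        a = simulate_stuart_landau(p, _zero_drive(10000), 7)
        b = simulate_stuart_landau(p, _zero_drive(10000), 7)
        c = simulate_stuart_landau(p, _zero_drive(10000), 8)
        assert np.array_equal(a.lfp.values, b.lfp.values)
        assert not np.array_equal(a.lfp.values, c.lfp.values)

    def test_divergent_step_aborts_with_diagnostic(self):
        p = StuartLandauParams(mu=1e5, noise_sigma=0.0, z0=1.0)
        with pytest.raises(FloatingPointError, match="dt"):
            simulate_stuart_landau(p, _zero_drive(5000), 1,
                                   MeasurementModel(enabled=False))


class TestEIMass:
    def test_no_drive_no_gamma(self):
        run = simulate_ei_mass(EIMassParams(), _zero_drive(), 3)
        assert run.meta["oscillating"] is False

    def test_ramp_evokes_gamma_in_band(self):
        from gammaclamp.spectral import instantaneous_freq_power
        prot = RampProtocol(ramp_plateau_s=4.0)
        run = simulate_ei_mass(EIMassParams(), make_ramp(prot), 3)
        assert run.meta["oscillating"] is True
        ft, _ = instantaneous_freq_power(run.lfp)
        f = np.nanmean(ft.values[ft.times() >= 4.5])
        assert 30.0 <= f <= 60.0

    def test_held_current_sign_conventions(self):
        prot = RampProtocol(ramp_plateau_s=4.0)
        run = simulate_ei_mass(EIMassParams(), make_ramp(prot), 3)
        assert np.all(run.i_exc_hold.values <= 0)   # inward at -70 mV
        assert np.all(run.i_inh_hold.values >= 0)   # outward at 0 mV

    def test_baseline_inhibition_dominates_phasic_currents(self):
        prot = RampProtocol(ramp_plateau_s=4.0)
        run = simulate_ei_mass(EIMassParams(), make_ramp(prot), 3)
        exc = np.ptp(run.i_exc_hold.slice(5.0, 7.0).values)
        inh = np.ptp(run.i_inh_hold.slice(5.0, 7.0).values)
        assert inh > exc

    def test_spikes_sparse_and_near_trough(self):
        from gammaclamp.spikes import spike_phase_table
        prot = RampProtocol(ramp_plateau_s=4.0)
        run = simulate_ei_mass(EIMassParams(), make_ramp(prot), 3)
        times = np.sort(np.concatenate([s.spike_times for s in run.spikes]))
        sel = times[(times > 4.5) & (times < 7.8)]
        rate = sel.size / 3.3 / len(run.spikes)
        assert 1.0 < rate < 8.0
        tab = spike_phase_table(run.lfp, sel)
        pv = circular_mean(tab[tab.status == "ok"].phase_deg.values)
        assert pv.magnitude > 0.25
        # preferred phase close to the trough (0 deg), allowing the
        # synaptic/measurement lag between E and the constructed LFP
        assert min(pv.angle_deg, 360 - pv.angle_deg) < 55.0

    def test_seed_replay(self):
        prot = RampProtocol(ramp_plateau_s=4.0)
        a = simulate_ei_mass(EIMassParams(), make_ramp(prot), 5)
        b = simulate_ei_mass(EIMassParams(), make_ramp(prot), 5)
        assert np.array_equal(a.lfp.values, b.lfp.values)
        assert all(np.array_equal(x.spike_times, y.spike_times)
                   for x, y in zip(a.spikes, b.spikes))


class TestMakeRamp:
    def test_linear_midpoint(self):
        ramp = make_ramp(RampProtocol(duration_s=8.0, ramp_peak_command=1.0))
        assert ramp.values[ramp.index_at(4.0)] == pytest.approx(0.5, abs=1e-3)

    def test_plateau_saturates(self):
        ramp = make_ramp(RampProtocol(ramp_plateau_s=4.0))
        assert ramp.values[ramp.index_at(6.0)] == pytest.approx(1.0)

    @given(start=st.floats(0.0, 3.0), peak=st.floats(0.1, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_ramp_nondecreasing_and_zero_before_onset(self, start, peak):
        prot = RampProtocol(duration_s=8.0, ramp_start_s=start,
                            ramp_peak_command=peak)
        ramp = make_ramp(prot, dt=1e-3)
        assert np.all(np.diff(ramp.values) >= 0)
        assert np.all(ramp.values[ramp.times() < start] == 0.0)


class TestPhaseLockedSpikes:
    def _track(self, duration=100.0, f=40.0):
        n = int(duration / 1e-4)
        return TimeSeries((np.arange(n) * 1e-4 * f * 360.0) % 360.0,
                          1e-4, "deg")

    def test_uniform_phases_at_zero_kappa(self):
        st_ = generate_phase_locked_spikes(self._track(), 10.0, 0.0, 0.0, seed=4)
        pv = circular_mean((st_.spike_times * 40 * 360) % 360)
        assert pv.magnitude < 3.0 / np.sqrt(st_.n)

    def test_concentration_limit(self):
        st_ = generate_phase_locked_spikes(self._track(), 10.0, 50.0, 30.0, seed=4)
        pv = circular_mean((st_.spike_times * 40 * 360) % 360)
        assert pv.magnitude > 0.95
        assert abs(pv.angle_deg - 30.0) < 5.0

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 4.0])
    def test_mean_rate_conserved_across_modulation_depths(self, kappa):
        st_ = generate_phase_locked_spikes(self._track(), 2.0, kappa, 0.0, seed=9)
        # Poisson count interval: 200 +/- 4*sqrt(200)
        assert abs(st_.n - 200) < 4 * np.sqrt(200)

    def test_vonmises_resultant_recovery(self):
        st_ = generate_phase_locked_spikes(self._track(), 20.0, 2.0, 90.0, seed=2)
        assert st_.n > 1500
        pv = circular_mean((st_.spike_times * 40 * 360) % 360)
        assert abs(pv.magnitude - vonmises_resultant_length(2.0)) < 0.03

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_phase_locked_spikes(self._track(1.0), -1.0, 1.0, 0.0, seed=1)
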