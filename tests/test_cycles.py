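import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammaclamp.core import CycleAverage, PhaseVector, TimeSeries
from gammaclamp.cycles import (accept_cycles, conductance, current_vector,
                               cycle_average, delta_vector, detect_troughs,
                               ei_orbit, phasic_component)


def _phase_signal(periods_s, dt=1e-4, phase_fn=np.cos, pre=500, post=500):
    """Signal built cycle by cycle: phase runs 0..360 between troughs.

    Returns (TimeSeries of -cos(phase) so troughs sit at phase 0,
    instantaneous phase array in degrees)."""
    segs = [np.zeros(pre)]
    phases = [np.zeros(pre)]
    for p in periods_s:
        n = int(round(p / dt))
        ph = np.arange(n) / n * 360.0
        phases.append(ph)
        segs.append(-np.cos(np.deg2rad(ph)))
    segs.append(np.zeros(post))
    phases.append(np.zeros(post))
    return (TimeSeries(np.concatenate(segs), dt, "mV"),
            np.concatenate(phases))


class TestDetectTroughs:
    def test_clean_sinusoid_trough_count_and_spacing(self, tone):
        lfp = tone(40.0, duration_s=1.0)
        tr = detect_troughs(lfp)
        assert abs(tr.size - 40) <= 1
        spacing_ms = np.diff(tr[1:-1]) * 0.1  # interior; edges see filter roll-in
        assert np.all(np.abs(spacing_ms - 25.0) < 0.5)

    def test_amplitude_jitter_does_not_change_count(self):
        rng = np.random.default_rng(7)
        dt = 1e-4
        t = np.arange(10000) * dt
        env = 1.0 + 0.2 * np.repeat(rng.uniform(-1, 1, 41), 250)[:10000]
        lfp = TimeSeries(env * np.cos(2 * np.pi * 40 * t), dt, "mV")
        ref = detect_troughs(TimeSeries(np.cos(2 * np.pi * 40 * t), dt, "mV"))
        assert detect_troughs(lfp).size == ref.size

    def test_constant_signal_empty(self):
        assert detect_troughs(TimeSeries(np.full(5000, 2.0), 1e-4, "mV")).size == 0


class TestAcceptCycles:
    def test_uniform_periods_all_accepted(self):
        troughs = np.cumsum([1000, 250, 250, 250, 250])
        cs = accept_cycles(troughs, dt=1e-4)
        assert cs.modal_period_s == pytest.approx(0.025, abs=1e-3)
        assert cs.accepted.all()

    def test_deviant_period_rejected(self):
        # periods 25, 25, 25, 31 ms: 31 > 1.2 * 25 -> rejected
        troughs = np.cumsum([1000, 250, 250, 250, 310])
        cs = accept_cycles(troughs, dt=1e-4)
        assert list(cs.accepted) == [True, True, True, False]

    def test_boundary_is_inclusive(self):
        # 30 ms <= 1.2 * 25 ms -> accepted
        troughs = np.cumsum([1000, 250, 250, 300])
        cs = accept_cycles(troughs, dt=1e-4)
        assert cs.accepted.all()

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            accept_cycles(np.array([0, 250, 500]), dt=1e-4)

    @given(st.lists(st.integers(200, 320), min_size=4, max_size=40),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_filter(self, periods, _seed):
        troughs = np.concatenate([[1000], 1000 + np.cumsum(periods)])
        cs = accept_cycles(troughs, dt=1e-4)
        # brute force: histogram mode with the same 1 ms bins
        p = np.diff(troughs) * 1e-4
        bin_s = 1e-3
        edges = np.arange(p.min() - bin_s, p.max() + 2 * bin_s, bin_s)
        counts, edges = np.histogram(p, bins=edges)
        modal = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        expected = np.abs(p - modal) <= 0.20 * modal
        assert np.array_equal(cs.accepted, expected)


class TestCycleAverage:
    def test_cosine_current_reproduced_per_bin(self):
        lfp, phase = _phase_signal([0.025] * 60)
        current = TimeSeries(np.cos(np.deg2rad(phase)), lfp.dt, "pA")
        cs = accept_cycles(detect_troughs(lfp), dt=lfp.dt)
        avg = cycle_average(current, cs)
        expect = np.cos(np.deg2rad(avg.phase_bins_deg))
        assert np.max(np.abs(avg.mean_current - expect)) < 0.01

    def test_noise_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(3)
        lfp, _ = _phase_signal([0.025] * 220)
        noise = TimeSeries(rng.standard_normal(lfp.n), lfp.dt, "pA")
        cs = accept_cycles(detect_troughs(lfp), dt=lfp.dt)
        avg = cycle_average(noise, cs)
        # per-bin SD ~ 1/sqrt(n_cycles * samples_per_bin)
        assert avg.n_cycles >= 200
        assert avg.mean_current.std() < 3.0 / np.sqrt(avg.n_cycles)

    def test_rejected_cycles_are_masked_out(self):
        periods = [0.025] * 10 + [0.040] + [0.025] * 10
        lfp, phase = _phase_signal(periods)
        current = TimeSeries(np.cos(np.deg2rad(phase)), lfp.dt, "pA")
        cs = accept_cycles(detect_troughs(lfp), dt=lfp.dt)
        assert not cs.accepted.all()
        avg1 = cycle_average(current, cs)
        # corrupt only the rejected cycle
        vals = current.values.copy()
        bad = np.nonzero(~cs.accepted)[0][0]
        i0, i1 = cs.trough_indices[bad], cs.trough_indices[bad + 1]
        vals[i0:i1] = 999.0
        avg2 = cycle_average(current.copy_with(vals), cs)
        assert np.array_equal(avg1.mean_current, avg2.mean_current)


class TestPhasicComponent:
    def _avg(self, vals, hold):
        phi = np.arange(64) / 64 * 360.0
        return CycleAverage(phi, vals(np.deg2rad(phi)), 10, holding_mv=hold)

    def test_constant_current_zero_phasic(self):
        avg = self._avg(lambda p: np.full_like(p, -30.0), -70.0)
        assert np.allclose(phasic_component(avg).mean_current, 0.0)

    def test_inward_at_minus70_subtracts_least_negative(self):
        avg = self._avg(lambda p: -(10 + 5 * np.cos(p)), -70.0)
        ph = phasic_component(avg)
        assert ph.mean_current.max() == pytest.approx(10.0)
        assert ph.phase_bins_deg[np.argmax(ph.mean_current)] == 0.0
        assert ph.mean_current[32] == pytest.approx(0.0)  # zero at 180 deg

    def test_outward_at_zero_subtracts_minimum(self):
        avg = self._avg(lambda p: 20 + 8 * np.sin(p), 0.0)
        ph = phasic_component(avg)
        assert ph.mean_current[48] == pytest.approx(0.0)  # zero at 270 deg
        assert ph.mean_current.max() == pytest.approx(16.0)
        assert np.all(ph.mean_current >= 0)


class TestCurrentVector:
    def _phasic(self, vals):
        phi = np.arange(64) / 64 * 360.0
        return CycleAverage(phi, vals(np.deg2rad(phi)), 10)

    def test_delta_bump_angle(self):
        phi = np.arange(64) / 64 * 360.0
        vals = np.zeros(64)
        vals[16] = 5.0  # bump at 90 deg
        pv = current_vector(CycleAverage(phi, vals, 10))
        assert pv.angle_deg == pytest.approx(90.0)

    def test_raised_cosine_recovers_offset(self):
        pv = current_vector(self._phasic(
            lambda p: 3.0 * (1 + np.cos(p - np.deg2rad(30)))))
        assert pv.angle_deg == pytest.approx(30.0, abs=2.0)
        assert pv.magnitude == pytest.approx(3.0, rel=0.01)

    def test_uniform_phasic_flagged_undefined(self):
        pv = current_vector(self._phasic(lambda p: np.full_like(p, 2.0)))
        assert not pv.angle_defined


class TestDeltaVector:
    def test_identical_vectors_cancel(self):
        d = delta_vector(PhaseVector(5, 40), PhaseVector(5, 40))
        assert d.magnitude == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_addition(self):
        d = delta_vector(PhaseVector(10, 0), PhaseVector(5, 180))
        assert d.magnitude == pytest.approx(15.0)
        assert d.angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_subtraction(self):
        d = delta_vector(PhaseVector(5, 90), PhaseVector(5, 0))
        assert d.magnitude == pytest.approx(np.sqrt(50), rel=1e-9)
        assert d.angle_deg == pytest.approx(135.0)


@pytest.mark.parametrize("pa,ns", [(70.0, 1.0), (0.0, 0.0), (140.0, 2.0)])
def test_conductance_ohms_law(pa, ns):
    ts = TimeSeries(np.full(10, pa), 1e-4, "pA")
    g = conductance(ts, driving_force_mv=70.0)
    assert np.allclose(g.values, ns)
    assert g.units == "nS"


class TestEIOrbit:
    def _ca(self, vals):
        phi = np.arange(64) / 64 * 360.0
        return CycleAverage(phi, vals(np.deg2rad(phi)), 10, units="nS")

    def test_quadrature_pair_counterclockwise(self):
        orb = ei_orbit(self._ca(np.cos), self._ca(np.sin))
        assert orb.direction == "ccw"
        assert orb.g_e[0] == pytest.approx(1.0)
        assert orb.g_i[0] == pytest.approx(0.0, abs=1e-12)

    def test_scaling_preserves_direction(self):
        orb = ei_orbit(self._ca(np.cos), self._ca(lambda p: 2 * np.sin(p)))
        assert orb.direction == "ccw"

    def test_direction_follows_lead_sign(self):
        # excitation peaking 45 deg earlier than inhibition -> ccw;
        # peaking later -> cw
        lead = ei_orbit(self._ca(lambda p: np.cos(p + np.deg2rad(45))),
                        self._ca(np.cos))
        lag = ei_orbit(self._ca(lambda p: np.cos(p - np.deg2rad(45))),
                       self._ca(np.cos))
        assert lead.direction == "ccw"
        assert lag.direction == "cw"

    def test_bin_mismatch_rejected(self):
        phi32 = np.arange(32) / 32 * 360.0
        a = self._ca(np.cos)
        b = CycleAverage(phi32, np.sin(np.deg2rad(phi32)), 5, units="nS")
        with pytest.raises(ValueError):
            ei_orbit(a, b)


def test_sinusoidal_phasic_current_parameter_recovery():
    """End-to-end: jittered-gamma LFP plus injected sinusoidal phasic
    current (A, phi0) on a noisy baseline is recovered by trough
    detection + cycle averaging + the current vector within 10%/10 deg."""
    rng = np.random.default_rng(21)
    periods = rng.normal(0.025, 0.0012, 150).clip(0.021, 0.029)
    lfp, phase = _phase_signal(list(periods))
    amp_true, phi0_true = 8.0, 120.0
    current = (-20.0 - amp_true * (1 + np.cos(np.deg2rad(phase - phi0_true)))
               + rng.normal(0, 2.0, lfp.n))
    cs = accept_cycles(detect_troughs(lfp), dt=lfp.dt)
    assert cs.n_accepted >= 100
    avg = cycle_average(TimeSeries(current, lfp.dt, "pA"), cs, holding_mv=-70.0)
    pv = current_vector(phasic_component(avg))
    assert pv.magnitude == pytest.approx(amp_true, rel=0.10)
    assert abs((pv.angle_deg - phi0_true + 180) % 360 - 180) < 10.0
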