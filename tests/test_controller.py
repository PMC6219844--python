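import math

import numpy as np
import pytest

from gammaclamp.controller import (ControllerConfig, OpsinModel, command,
                                   lfp_derivative, opsin_filter,
                                   run_closed_loop)
from gammaclamp.core import RampProtocol, TimeSeries
from gammaclamp.synth import (MeasurementModel, StuartLandauParams,
                              StuartLandauPlant, make_ramp, run_open_loop)
from gammaclamp.controller import opsin_filter as _opsin_filter


def _ts(values, dt=1e-4, units="mV"):
    return TimeSeries(np.asarray(values, dtype=float), dt, units)


class TestLfpDerivative:
    def test_constant_signal_zero_slope(self):
        d = lfp_derivative(_ts(np.full(1000, 3.7)))
        assert np.allclose(d.values, 0.0)

    def test_linear_ramp_recovers_slope(self):
        # slope 0.5 mV/ms on the 10 kHz grid
        x = _ts(np.arange(1000) * 0.05)
        d = lfp_derivative(x, 2.0)
        assert np.allclose(d.values[25:], 0.5)

    def test_sinusoid_amplitude_matches_boxcar_response(self):
        t = np.arange(20000) * 1e-4
        d = lfp_derivative(_ts(np.sin(2 * np.pi * 40 * t)), 2.0)
        w, dt, wlen = 2 * np.pi * 40, 1e-4, 20
        expected = abs((1 - np.exp(-1j * w * dt * wlen)) / (wlen * dt * 1000))
        assert np.abs(d.values[5000:]).max() == pytest.approx(expected, rel=1e-3)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            lfp_derivative(_ts(np.zeros(100)), 0.05)


class TestCommandLaw:
    CFG = ControllerConfig(k1=1.0, k2=25.0, clamp_window=(0.0, 10.0))

    def test_identity_without_feedback(self):
        cfg = ControllerConfig(k1=0.0, k2=0.0, clamp_window=(0.0, 10.0))
        assert command(0.73, 5.0, -2.0, cfg, t=1.0) == 0.73

    def test_threshold_linear_clipping(self):
        cfg = ControllerConfig(k1=4.0, k2=0.0, clamp_window=(0.0, 10.0))
        assert command(1.0, -0.5, 0.0, cfg, t=1.0) == 0.0

    def test_printed_formula_direct_evaluation(self):
        # ramp 1, lfp 0.2 mV, dlfp 0.01 mV/ms, k1=1/mV, k2=25 ms/mV
        assert command(1.0, 0.2, 0.01, self.CFG, t=1.0) == pytest.approx(1.45)

    def test_unity_factor_outside_window(self):
        cfg = ControllerConfig(k1=4.0, k2=10.0, clamp_window=(2.0, 3.0))
        assert command(0.5, 1.0, 1.0, cfg, t=1.0) == 0.5


class TestOpsinFilter:
    def test_step_reaches_1_minus_1_over_e_at_tau(self):
        x = _ts(np.ones(1000), units="V")
        y = opsin_filter(x, OpsinModel(5.0, 5.0))
        i_tau = int(round(5e-3 / 1e-4))
        assert y.values[i_tau - 1] == pytest.approx(1 - math.exp(-1), rel=0.02)

    def test_sinusoid_phase_lag_first_order(self):
        t = np.arange(20000) * 1e-4
        x = _ts(1 + 0.5 * np.sin(2 * np.pi * 40 * t), units="V")
        y = opsin_filter(x, OpsinModel(2.0, 2.0))
        sl = slice(10000, None)
        ref = np.exp(-2j * np.pi * 40 * t[sl])
        zx = np.sum((x.values[sl] - x.values[sl].mean()) * ref)
        zy = np.sum((y.values[sl] - y.values[sl].mean()) * ref)
        lag = -np.degrees(np.angle(zy / zx))
        assert lag == pytest.approx(np.degrees(np.arctan(2 * np.pi * 40 * 2e-3)),
                                    abs=1.5)

    def test_zero_input_zero_output_and_monotone(self):
        y = opsin_filter(_ts(np.zeros(100), units="V"), OpsinModel())
        assert np.all(y.values == 0.0)
        y2 = opsin_filter(_ts(np.abs(np.sin(np.arange(1000) / 7)), units="V"),
                          OpsinModel())
        assert np.all(y2.values >= 0.0)


def _sl_plant(noise=0.0):
    return StuartLandauPlant(
        StuartLandauParams(mu=50.0, drive_gain=1500.0, noise_sigma=noise),
        measurement=MeasurementModel())


class TestClosedLoop:
    PROT = RampProtocol(duration_s=3.0, clamp_window=(1.0, 2.5))

    def test_zero_gain_is_bit_exact_ramp_passthrough(self):
        opsin = OpsinModel()
        run_fb = run_closed_loop(_sl_plant(noise=1.0),
                                 ControllerConfig(k1=0.0, k2=0.0),
                                 opsin, self.PROT, seed=5)
        ramp = make_ramp(self.PROT)
        drive = _opsin_filter(ramp, opsin)
        run_ol = run_open_loop(_sl_plant(noise=1.0), drive, seed=5)
        assert np.array_equal(run_fb.led_command.values, ramp.values)
        assert np.array_equal(run_fb.lfp.values, run_ol.lfp.values)

    def test_zero_mean_modulation_of_mean_command(self):
        """For a zero-mean LFP the clamp leaves the average LED command
        within 1% of the plain ramp average over the window."""
        run = run_closed_loop(_sl_plant(),
                              ControllerConfig(k1=0.6, k2=0.0),
                              OpsinModel(), self.PROT, seed=5)
        ramp = make_ramp(self.PROT)
        lo, hi = ramp.index_at(1.0), ramp.index_at(2.5)
        led = run.led_command.values[lo:hi].mean()
        base = ramp.values[lo:hi].mean()
        assert abs(led / base - 1.0) < 0.01

    def test_causality_by_truncation_equivalence(self):
        """Controller output up to time T is unchanged by what the LFP
        does after T (checked by comparing a run against a twin whose
        plant noise differs only after T)."""
        prot = RampProtocol(duration_s=2.0, clamp_window=(0.5, 2.0))
        cfg = ControllerConfig(k1=0.6, k2=10.0)

        class SwitchNoisePlant(StuartLandauPlant):
            def __init__(self, flip_after, seed_extra):
                super().__init__(StuartLandauParams(mu=50.0, drive_gain=1500.0,
                                                    noise_sigma=1.0),
                                 measurement=MeasurementModel())
                self._flip_after = flip_after
                self._seed_extra = seed_extra

            def reset(self, n, seed):
                super().reset(n, seed)
                i0 = int(self._flip_after / self.dt)
                alt = np.random.default_rng(self._seed_extra).standard_normal(
                    self.n - i0) * abs(self._noise[0])
                self._noise = self._noise.copy()
                self._noise[i0:] = alt + 1j * alt

        t_cut = 1.5
        a = run_closed_loop(SwitchNoisePlant(t_cut, 1), cfg, OpsinModel(), prot, 3)
        b = run_closed_loop(SwitchNoisePlant(t_cut, 2), cfg, OpsinModel(), prot, 3)
        i_cut = int(t_cut / 1e-4)
        assert np.array_equal(a.led_command.values[:i_cut + 1],
                              b.led_command.values[:i_cut + 1])
        assert not np.array_equal(a.led_command.values[i_cut:],
                                  b.led_command.values[i_cut:])

    def test_dt_mismatch_rejected(self):
        plant = _sl_plant()
        cfg = ControllerConfig(loop_rate_hz=5000.0, deriv_avg_ms=2.0)
        with pytest.raises(ValueError):
            run_closed_loop(plant, cfg, OpsinModel(), self.PROT, seed=1)

    def test_in_phase_clamp_raises_frequency(self, rotation_study):
        """k1 > 0 (in-phase drive at beta = +90 deg) raises the
        oscillation frequency during the window."""
        df_at_zero = rotation_study["df"][0]  # psi = 0 entry of the sweep
        assert df_at_zero > 0


def test_controller_config_validation():
    with pytest.raises(ValueError):
        ControllerConfig(deriv_avg_ms=0.15)  # not a multiple of 0.1 ms
    with pytest.raises(ValueError):
        ControllerConfig(feedback_delay_steps=0)
    with pytest.raises(ValueError):
        OpsinModel(tau_on_ms=0.0)
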