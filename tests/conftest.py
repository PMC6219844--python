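import numpy as np
import pytest

from gammaclamp.core import TimeSeries


@pytest.fixture
def tone():
    """Factory for pure-tone TimeSeries at the 10 kHz grid."""

    def make(freq_hz=40.0, amp=1.0, phase_rad=0.0, duration_s=2.0,
             dt=1e-4, units="mV"):
        t = np.arange(int(round(duration_s / dt))) * dt
        return TimeSeries(amp * np.cos(2 * np.pi * freq_hz * t + phase_rad),
                          dt, units)

    return make


@pytest.fixture(scope="session")
def rotation_study():
    """Feedback-phase sweep of the Hopf plant (shared across tests)."""
    from gammaclamp.studies import run_sl_rotation_sweep
    return run_sl_rotation_sweep(seed=1)


@pytest.fixture(scope="session")
def prc_study(rotation_study):
    from gammaclamp.studies import run_sl_prc_study
    return run_sl_prc_study(seed=1, rotation=rotation_study)


@pytest.fixture(scope="session")
def ei_battery():
    """Clamped vs unclamped-twin trials on the E-I plant (stochastic,
    fixed seeds)."""
    from gammaclamp.studies import run_ei_clamp_battery
    return run_ei_clamp_battery(seed=1, n_trials=4)
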