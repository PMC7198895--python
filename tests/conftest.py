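import pytest

from dbiwin.simulators import PhasePairConfig, simulate_phase_pair
from dbiwin.window_optimizer import optimize


@pytest.fixture(scope="session")
def phase_series_short():
    """200 s of the coupled phase-oscillator pair at default settings."""
    return simulate_phase_pair(PhasePairConfig(duration=200.0, seed=11))


@pytest.fixture(scope="session")
def phase_series_long():
    """A full-length (2000 s) record of the default test system."""
    return simulate_phase_pair(PhasePairConfig(duration=2000.0, seed=1))


@pytest.fixture(scope="session")
def stationary_series():
    """Constant-parameter variant (no modulation) for stationarity checks."""
    cfg = PhasePairConfig(duration=400.0, seed=7, mod_omega=0.0, mod_a3=0.0)
    return simulate_phase_pair(cfg)


@pytest.fixture(scope="session")
def optimized(phase_series_long):
    """Two-pass optimization of the long record: (plan, optimized run)."""
    return optimize(phase_series_long)
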