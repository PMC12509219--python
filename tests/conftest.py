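import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from flp import (
    FluorophoreSpecies,
    InstrumentConfig,
    ModulationContext,
    calibrate,
    simulate_dark,
    simulate_phase_ramp,
)


@pytest.fixture(scope="session")
def ctx():
    return ModulationContext()


@pytest.fixture(scope="session")
def standard():
    return FluorophoreSpecies("coumarin6", 2.40)


@pytest.fixture(scope="session")
def config():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def noiseless_calibration(config, standard, ctx):
    """Calibration of the default instrument from noiseless recordings."""
    ramp = simulate_phase_ramp(config, standard, noisy=False)
    dark = simulate_dark(config, duration=1.0, noisy=False)
    return calibrate(ramp, dark, standard, ctx)


def fourier_phasor_oracle(lifetime_ns, ctx, n=200_000):
    """Independent numeric phasor: project the periodized exponential decay
    onto cos/sin at the modulation frequency."""
    period_ns = 1e9 / ctx.modulation_frequency
    t = (np.arange(n) + 0.5) * (period_ns / n)
    decay = np.exp(-t / lifetime_ns) / (1.0 - np.exp(-period_ns / lifetime_ns))
    w_t = 2 * np.pi * t / period_ns
    total = decay.sum()
    g = float((decay * np.cos(w_t)).sum() / total)
    s = float((decay * np.sin(w_t)).sum() / total)
    return g, s
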