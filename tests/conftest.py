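import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import promyelin as pm

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def noiseless(channel, duration_s=180000.0, dt_s=4.0, **overrides):
    """Deterministic skeleton trace: stochastic components switched off."""
    p = dataclasses.replace(
        pm.default_params(channel), noise_sd=0.0, spike_rate=0.0, **overrides
    )
    return pm.simulate_channel(channel, p, duration_s=duration_s, dt_s=dt_s, seed=0)


@pytest.fixture(scope="session")
def full_scale_ensemble():
    """Default eight-channel ensemble over the full 180 ks span (coarse grid)."""
    return pm.simulate_ensemble(duration_s=180000.0, dt_s=8.0, seed=7)
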