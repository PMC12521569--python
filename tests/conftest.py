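import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mealphot.session import SessionMeta
from mealphot.signal import PulseSchedule
from mealphot.simgen import GroupParams, SimConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def schedule():
    return PulseSchedule()


@pytest.fixture
def meta():
    return SessionMeta(mouse_id="m00", session_id="m00_s00", diet="NCD",
                       condition="NCD", body_weight=25.0, sex="M")


@pytest.fixture
def small_config():
    """Fast 60-trial trace-level config with deterministic-ish triggering."""
    def make(**overrides):
        gp = overrides.pop("gp", GroupParams())
        kw = dict(n_mice=1, sessions_per_mouse=1, n_trials=60,
                  group_params={"NCD": gp}, seed=7, level="trace",
                  simulate_isosbestic=False, mouse_effect_sd=0.0,
                  session_vigor_jitter_sd=0.0)
        kw.update(overrides)
        return SimConfig(**kw)
    return make
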