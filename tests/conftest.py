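import numpy as np
import pytest

from pulseddm import DDMParams, TaskConfig, generate_session, simulate_choices_ddm

#: Baseline-regime generating parameters used across recovery tests
#: (leaky accumulation with tau ~ 6.7 s, modest noise, small lapse).
BASELINE = DDMParams(lam=-0.15, sigma_a2=0.5, sigma_s2=1.0, bias=0.0, lapse=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_session():
    """A mixed-condition session of 300 trials (stimuli only)."""
    gen = np.random.default_rng(1)
    return generate_session(TaskConfig(), n_trials=300, rng=gen)


@pytest.fixture(scope="session")
def baseline_trials():
    """5000 long-cue baseline trials with drift-diffusion agent choices."""
    gen = np.random.default_rng(2)
    cfg = TaskConfig(p_long=1.0, light_fraction=0.0)
    ts = generate_session(cfg, n_trials=5000, rng=gen)
    return simulate_choices_ddm(ts, BASELINE, rng=gen)
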