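import numpy as np
import pytest

import tremorkit as tk


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def tremor_session():
    """Strong-tremor session with onset at 25 min, seeded."""
    return tk.simulate_session(
        tk.strong_tremor_profile(25.0),
        tk.NoiseProfile(),
        tk.SessionPlan.regular(seed=7),
    )


@pytest.fixture(scope="session")
def noise_session():
    """Noise-only session on the standard schedule, seeded."""
    return tk.simulate_session(
        None, tk.NoiseProfile(), tk.SessionPlan.regular(seed=8))


@pytest.fixture(scope="session")
def fast_config():
    return tk.PipelineConfig(n_boot=0, tremor_band=(10.0, 14.0))
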