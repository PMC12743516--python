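import numpy as np
import pytest

from afmvpa import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separated_config():
    """Two well-separated phenotypes: 10 informative variables at 0.05 vs 0.60."""
    prev_low = np.full(syn.N_VARS, 0.05)
    prev_high = np.full(syn.N_VARS, 0.05)
    prev_high[:10] = 0.60
    return syn.SimulationConfig(
        n_individuals=500,
        seed=42,
        prevalence_low=prev_low,
        prevalence_high=prev_high,
    )


@pytest.fixture(scope="session")
def separated_cohort(separated_config):
    return syn.simulate_cohort(separated_config)
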