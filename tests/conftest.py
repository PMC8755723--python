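import numpy as np
import pytest

from deepseep import synthetic_data as syn


@pytest.fixture(scope="session")
def biased_genome():
    """Genome with bias strength 0.5 (shared: generation is the slow part)."""
    return syn.generate_genome(seed=11, bias_strength=0.5)


@pytest.fixture(scope="session")
def noise_free_ptr2_profile():
    return syn.simulate_coverage(250_000, mean_depth=50.0, true_ptr=2.0, noise="none")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
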