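import numpy as np
import pytest

from admixfine.cohort import AncestralFrequencies
from admixfine.simcohort import DiseaseModel, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mixed cohort (singletons + families) reused by read-only tests."""
    cfg = SimConfig(n_individuals=150, n_families=25, sibship_size=2,
                    n_markers=60, seed=42,
                    freq_table=AncestralFrequencies.random(
                        60, np.random.default_rng(7), 0.1, 0.9),
                    disease=DiseaseModel(gamma=1.0))
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
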