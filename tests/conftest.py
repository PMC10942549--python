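import numpy as np
import pytest

from dfncstates.synthetic import (
    CohortDesign,
    MarkovDesign,
    StateArchetype,
    gen_cohort,
    gen_network_partition,
    gen_state_covariances,
)


@pytest.fixture(scope="session")
def small_partition():
    """12 components in 3 networks — small enough for exhaustive checks."""
    return gen_network_partition(12, 3, seed=0)


@pytest.fixture(scope="session")
def small_archetypes():
    """Three well-separated scalar-strength archetypes for small cohorts."""
    return [
        StateArchetype("a", intra_block_strength=0.7, inter_block_strength=0.0,
                       noise_sd=0.05),
        StateArchetype("b", intra_block_strength=0.2, inter_block_strength=0.5,
                       noise_sd=0.05),
        StateArchetype("c", intra_block_strength=0.4, inter_block_strength=-0.3,
                       noise_sd=0.05),
    ]


@pytest.fixture(scope="session")
def small_covariances(small_partition, small_archetypes):
    return gen_state_covariances(small_partition, small_archetypes)


@pytest.fixture(scope="session")
def tiny_cohort(small_partition, small_archetypes):
    """6 subjects x 120 timepoints x 12 components, with timecourses."""
    design = CohortDesign(n_subjects=6, T=120, seed=42)
    return gen_cohort(design, small_partition, small_archetypes,
                      MarkovDesign(K=3, subject_concentration=50.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
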