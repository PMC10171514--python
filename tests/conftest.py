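import numpy as np
import pytest

from neuromediate import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced-parcellation cohort with both connectome modalities."""
    config = synthetic.CohortConfig(
        n_subjects=120,
        seed=42,
        nodes_cortical_per_hemi=30,
        nodes_subcortical_per_hemi=4,
    )
    cohort, truth = synthetic.generate_cohort(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def phenotype_cohort():
    """A larger phenotype-only cohort for association-level checks."""
    config = synthetic.CohortConfig(
        n_subjects=4000,
        seed=7,
        include_structural=False,
        include_functional=False,
    )
    cohort, truth = synthetic.generate_cohort(config)
    return config, cohort, truth
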