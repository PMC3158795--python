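import numpy as np
import pytest

import episcan as e


@pytest.fixture(scope="session")
def small_cohort():
    """Unrelated 300 x 120 cohort with no genetic trait structure."""
    config = e.SimulationConfig(
        n_individuals=300, n_snps=120, maf_range=(0.2, 0.5), seed=11
    )
    genotypes, phenotypes = e.simulate_cohort(config)
    return config, genotypes, phenotypes


@pytest.fixture(scope="session")
def null_trait_cohort():
    """600 x 300 clean panel plus an iid normal trait (global null)."""
    config = e.SimulationConfig(
        n_individuals=600, n_snps=300, maf_range=(0.3, 0.5), seed=0
    )
    genotypes = e.simulate_genotypes(config)
    y = np.random.default_rng(100).normal(size=600)
    trait = e.PreparedTrait(
        values=y, sample_ids=genotypes.sample_ids, stage="polygenic_residual"
    )
    return genotypes, trait
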