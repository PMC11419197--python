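import numpy as np
import pytest

from gxedecomp import CohortConfig, generate_cohort, generate_variant_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240909)


@pytest.fixture(scope="session")
def small_panel():
    """60 variants on 3 mock chromosomes, moderate LD, 3,000 samples."""
    return generate_variant_panel(
        n_samples=3000, n_variants=60, ld_rho=0.7, maf_range=(0.1, 0.5), seed=11
    )


@pytest.fixture(scope="session")
def interaction_cohort(small_panel):
    """Cohort with a genotype x diet interaction on the mediator (partial
    variance fraction 0.006 -> upstream NCP ~ 18 at n=3,000)."""
    return generate_cohort(small_panel, CohortConfig(v_gxd=0.006), seed=7)


@pytest.fixture(scope="session")
def null_cohort(small_panel):
    """Cohort with no genotype x diet interaction."""
    return generate_cohort(small_panel, CohortConfig(v_gxd=0.0), seed=8)
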