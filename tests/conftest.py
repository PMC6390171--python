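import numpy as np
import pandas as pd
import pytest

from nephroage.simulate import (
    CohortParams,
    Effect,
    promoter_methylation_scenario,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_params():
    return CohortParams(
        n_samples=120,
        n_genes=40,
        n_cpgs=10,
        n_variants=30,
        ld_block_size=3,
        seed=7,
        effects=[
            Effect("age", "cpg:cpg_0000", 0.05),
            Effect("variant:rs000000", "cpg:cpg_0000", 0.6),
            Effect("cpg:cpg_0000", "gene:gene_0000", -2.0),
        ],
    )


@pytest.fixture(scope="session")
def small_bundle(small_params):
    return simulate_cohort(small_params, with_traits=True)


@pytest.fixture(scope="session")
def scenario():
    params = promoter_methylation_scenario(n_samples=260, seed=3)
    return params, simulate_cohort(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
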