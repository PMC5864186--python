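import numpy as np
import pandas as pd
import pytest

from ecosig import (
    CohortSpec,
    MetagenomeMeta,
    MonteCarloConfig,
    ProfileMatrix,
    generate_cohort,
    run_monte_carlo,
)


@pytest.fixture(scope="session")
def default_cohort() -> ProfileMatrix:
    """Habitat-structured cohort drawn from the default synthetic spec."""
    return generate_cohort(CohortSpec(seed=20170))


@pytest.fixture(scope="session")
def mc_config(default_cohort) -> MonteCarloConfig:
    return MonteCarloConfig.from_cohort(
        default_cohort,
        n_iterations=3,
        n_env_per_iteration=40,
        n_polluted_per_type=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def mc_iterations(mc_config):
    return run_monte_carlo(mc_config)


@pytest.fixture()
def tiny_matrix() -> ProfileMatrix:
    """Three hand-written profiles over four ORFs."""
    data = pd.DataFrame(
        {
            "ORF_1": [1.0, 1.0, 0.0],
            "ORF_2": [1.0, 0.0, 0.0],
            "ORF_3": [0.0, 0.0, 2.0],
            "ORF_4": [0.0, 0.0, 0.0],
        },
        index=["a", "b", "c"],
    )
    meta = pd.DataFrame(
        {
            "habitat_group": ["g1", "g1", "g2"],
            "total_bp": [1e6, 1e6, 1e6],
            "assembled": [False, False, False],
        },
        index=data.index,
    )
    return ProfileMatrix(data, meta)


@pytest.fixture()
def simple_meta() -> MetagenomeMeta:
    return MetagenomeMeta("ds1", "env_virome", 2_000_000)
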