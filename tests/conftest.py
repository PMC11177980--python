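import numpy as np
import pytest

from acsselect import (
    EnsembleConfig,
    generate_cohort,
    impute_constant,
)
from acsselect.synthetic import external_config, internal_config


@pytest.fixture(scope="session")
def small_pair():
    """Small imputed internal/external cohort pair for protocol tests."""
    internal = impute_constant(generate_cohort(internal_config(n=400, seed=101)))
    external = impute_constant(generate_cohort(external_config(n=300, seed=102)))
    return internal, external


@pytest.fixture(scope="session")
def tiny_ensemble_config():
    """Fast single-point ensemble config (no grid search)."""
    return EnsembleConfig(
        learning_rate=0.2, depth=3, subsample=0.75, iterations=30,
        n_members=3, base_seed=7, grid=None,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_927)


def random_member_tensor(rng, m, n, k=2):
    """Random valid M x n x K probability tensor (Dirichlet rows)."""
    return rng.dirichlet(np.ones(k), size=(m, n))
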