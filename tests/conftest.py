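"""Shared fixtures: full-scale replicate ensembles reused across tests.

The heavy constructionist batches (2000 replicates of 10^4 generations)
are session-scoped so the distributional tests and the acceptance tests
share one simulation per configuration.  All seeds are fixed.
"""

import numpy as np
import pytest

from gendom import ExperimentConfig, run_batch

FIXTURE_SEED = 0
FIXTURE_REPLICATES = 2000


def _batch(**kwargs):
    cfg = ExperimentConfig(replicates=FIXTURE_REPLICATES, seed=FIXTURE_SEED,
                           **kwargs)
    return run_batch(cfg)


@pytest.fixture(scope="session")
def batch_random_alpha():
    """No drift, per-genotype weightings drawn from U[0, 1/2]."""
    return _batch(alpha_mode="random")


@pytest.fixture(scope="session")
def batch_alpha_third():
    """No drift, fixed alpha = 1/3."""
    return _batch(alpha=1 / 3)


@pytest.fixture(scope="session")
def batch_alpha_half():
    """No drift, fixed alpha = 1/2 (purely additive fitnesses)."""
    return _batch(alpha=0.5)


@pytest.fixture(scope="session")
def batch_half_drift_small():
    """alpha = 1/2 with Wright-Fisher drift, N = 10^4."""
    return _batch(alpha=0.5, population_size=10_000)


@pytest.fixture(scope="session")
def batch_half_drift_large():
    """alpha = 1/2 with Wright-Fisher drift, N = 10^5."""
    return _batch(alpha=0.5, population_size=100_000)


@pytest.fixture(scope="session")
def batch_third_drift_small():
    """alpha = 1/3 with Wright-Fisher drift, N = 10^4."""
    return _batch(alpha=1 / 3, population_size=10_000)


@pytest.fixture
def rng():
    return np.random.default_rng(FIXTURE_SEED)
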