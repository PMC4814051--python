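import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import txconcord as tx

settings.register_profile(
    "default",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    return tx.SimulationConfig(
        n_genes=300, n_modules=8, module_size_range=(8, 15),
        n_drugs=20, experiments_per_drug=6, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    logfc, meta, truth = tx.generate_training_cohort(small_config)
    return logfc, meta, truth


@pytest.fixture(scope="session")
def small_models(small_cohort):
    logfc, _, _ = small_cohort
    return tx.build_module_models(logfc)


@pytest.fixture(scope="session")
def small_scores(small_cohort, small_models):
    logfc, _, _ = small_cohort
    return tx.training_scores(small_models, logfc)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def two_block_logfc():
    """Two orthogonal planted module blocks, zero noise: 12 genes, two
    independent latent signals driving 6 genes each."""
    rng = np.random.default_rng(3)
    s1, s2 = rng.normal(size=30), rng.normal(size=30)
    w1 = np.array([1.0, 0.9, 1.1, -0.8, 1.0, 0.95])
    w2 = np.array([0.7, 1.2, 1.0, 1.05, -0.9, 0.85])
    X = np.vstack([np.outer(w1, s1), np.outer(w2, s2)])
    genes = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    cols = [f"e{i}" for i in range(30)]
    return tx.LogFCMatrix(pd.DataFrame(X, index=genes, columns=cols))
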