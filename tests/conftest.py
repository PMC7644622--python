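import numpy as np
import pytest
from hypothesis import settings

import genconn as g

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    """A modest cohort with a clearly detectable planted mode."""
    return g.SimulationConfig(
        n_subjects=300, n_snps=200, n_nodes=20, n_causal_snps=30,
        n_signal_connections=40, rho=0.7, seed=11)


@pytest.fixture(scope="session")
def cohort(small_cfg):
    return g.simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def pipeline_result(cohort):
    genotypes, connectomes, covariates, _, _, _ = cohort
    conn_vec, _ = g.vectorize(connectomes)
    return g.run_cca_pipeline(genotypes.dosages, conn_vec, covariates,
                              n_components=20)


@pytest.fixture(scope="session")
def conn_vec(cohort):
    _, connectomes, *_ = cohort
    vec, idx = g.vectorize(connectomes)
    return vec, idx


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
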