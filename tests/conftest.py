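import numpy as np
import pytest

import tgblup as tg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_data():
    """Desk-scale synthetic stand-in for the multi-environment study layout."""
    return tg.study_shaped_fixture(seed=7)


@pytest.fixture(scope="session")
def small_model2_data():
    """Small model-2 simulation used by several sampler/scoring tests."""
    geno = tg.simulate_genotypes(40, 120, (0.1, 0.9), seed=21)
    config = tg.SimulationConfig(
        n_lines=40, n_envs=2, n_markers=120, categories=3,
        beta=(0.5, 0.3), variances={"G": 0.5}, thresholds=(0.0, 1.0),
        replicates=3, seed=22,
    )
    pheno, truth = tg.simulate_dataset(config, geno)
    return pheno, geno, truth


@pytest.fixture(scope="session")
def small_model2_fit(small_model2_data):
    """A short but usable chain on the small model-2 data."""
    pheno, geno, _ = small_model2_data
    settings = tg.GibbsSettings(iterations=1500, burnin=500, thin=2, seed=5)
    return tg.fit(pheno, geno, 2, settings)
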