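import numpy as np
import pytest

import mmgee as mg


@pytest.fixture(scope="session")
def fixture_data():
    """Small mixed-endpoint dataset: M=3 endpoints, K=40 subjects, seed 1."""
    cfg = mg.ScenarioConfig(M=3, K=40, rho_between=0.5, effects="null", seed=1)
    return mg.generate_dataset(cfg)


@pytest.fixture(scope="session")
def fixture_fits(fixture_data):
    specs = mg.analysis_specs(fixture_data, 3)
    return [mg.fit_gee(s) for s in specs]


@pytest.fixture(scope="session")
def fixture_mmm(fixture_fits):
    return mg.stack_models(fixture_fits)


@pytest.fixture(scope="session")
def group_hyp():
    """H0: group coefficient zero in each of the three models."""
    return mg.group_contrast(3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
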