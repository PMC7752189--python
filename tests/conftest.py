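"""Shared fixtures: small synthetic studies and fast sampler settings.

MCMC-heavy fixtures are session-scoped so several tests can interrogate one
fitted object instead of refitting.
"""

import warnings

import numpy as np
import pytest

from sdmnet.inference import McmcConfig
from sdmnet.network import SkillsNetworkEstimator
from sdmnet.simulate import StudyDesign, default_network_spec, simulate_study


@pytest.fixture(scope="session")
def fast_mcmc() -> McmcConfig:
    """Short chains for unit tests that only need a rough posterior."""
    return McmcConfig(n_chains=3, iterations=1000, burn_in=500, seed=0)


@pytest.fixture(scope="session")
def default_spec():
    return default_network_spec()


@pytest.fixture(scope="session")
def tiny_study():
    """Small complete synthetic study: 8 physicians x 10 patients."""
    design = StudyDesign(n_physicians=8, patients_per_physician=10, seed=123)
    return simulate_study(design=design)


@pytest.fixture(scope="session")
def fitted_network(tiny_study, fast_mcmc):
    """Random-slope network fit of the tiny study (shared across tests)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = SkillsNetworkEstimator(model_selection="random", mcmc=fast_mcmc, seed=99)
        est.fit(tiny_study["patient_ratings"])
    return est


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
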