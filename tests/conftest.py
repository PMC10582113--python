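import numpy as np
import pytest

import isocast as ic


@pytest.fixture(scope="session")
def iznik():
    return ic.load_fixture("iznik_community")


@pytest.fixture(scope="session")
def perch():
    return ic.load_fixture("perch_sites")


@pytest.fixture(scope="session")
def iznik_baselines(iznik):
    return ic.baseline_from_community(iznik, lam=2.0)


@pytest.fixture
def fast_mcmc():
    """Short chains for unit tests; long-run settings are exercised in the
    acceptance layer."""
    return ic.MCMCConfig(n_chains=2, n_iter=1500, n_burn=500)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
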