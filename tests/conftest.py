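import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import popswitch as ps

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return ps.ModelPMFParams()


@pytest.fixture(scope="session")
def pmf_no_metal(default_params):
    return ps.make_pmf(default_params, metal_bound=False)


@pytest.fixture(scope="session")
def pmf_metal(default_params):
    return ps.make_pmf(default_params, metal_bound=True)


@pytest.fixture(scope="session")
def flat_pmf():
    """W = 0 on [0, 40] A."""
    grid = np.linspace(0.0, 40.0, 4001)
    return ps.PMFProfile(grid, np.zeros_like(grid))


@pytest.fixture(scope="session")
def competition_setup():
    """Default competition-assay conditions with the study's apparent Kd as
    ground truth; noise sd is 2% of the clean curve's dynamic range."""
    system = ps.EquilibriumSystem(metal_total=0.0, chelator_total=500.0,
                                  protein_total=500.0, kd_chelator=100.0,
                                  kd_protein=41.5)
    totals = np.linspace(0.0, 2500.0, 16)
    response = ps.ResponseModel()
    clean = np.array([ps.predict_signal(system.with_metal_total(m), response)
                      for m in totals])
    noise_sd = 0.02 * (clean.max() - clean.min())
    return {"system": system, "totals": totals, "response": response,
            "clean": clean, "noise_sd": noise_sd, "kd_true": 41.5}
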