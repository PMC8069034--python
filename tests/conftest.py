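import numpy as np
import pytest

from il13pkpd import (
    PopulationModel,
    ResidualModel,
    TrialDesign,
    reference_model,
    reference_params,
)


@pytest.fixture(scope="session")
def ref_params():
    return reference_params()


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def small_design():
    """A reduced design for fast estimation tests: two cohorts, 3+3 active,
    2 placebo, same sampling days."""
    return TrialDesign(cohorts=((105.0, 3), (600.0, 3)), placebo_n=2)


@pytest.fixture(scope="session")
def noisefree_model(ref_params):
    """Reference typical values with no IIV, no covariate effect and (near)
    no residual noise."""
    return PopulationModel(
        typical=ref_params.with_(ada_cl_effect=0.0),
        iiv_omega2={},
        residual=ResidualModel(pk_prop_sd=1e-6, pk_add_sd_ug_l=1e-8,
                               pd_prop_sd=1e-8),
    )


@pytest.fixture(scope="session")
def grid_281():
    return np.linspace(0.0, 281.0, 1500)
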