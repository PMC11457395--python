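import numpy as np
import pytest
from hypothesis import settings

import disweights as dw

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_catalog():
    """The packaged published weight table as a simulation catalog."""
    return dw.table2_catalog()


@pytest.fixture(scope="session")
def toy_catalog():
    """Six states with well-spread severities for small simulations."""
    dws = [0.02, 0.08, 0.2, 0.35, 0.55, 0.75]
    return [
        dw.HealthState(f"s{k}", f"state {k}", "Other",
                       reference_dw=v, true_dw=v)
        for k, v in enumerate(dws)
    ]


@pytest.fixture(scope="session")
def study_survey(fixture_catalog):
    """One full-scale synthetic survey shared by the heavier analyses.

    Study conditions: 3994 respondents, 18 tasks, the full published
    catalog, sigma calibrated to the observed test-retest consistency.
    """
    config = dw.SimulationConfig(seed=11)
    respondents, responses = dw.simulate_survey(fixture_catalog, config)
    return respondents, responses


@pytest.fixture(scope="session")
def study_fit(study_survey, fixture_catalog):
    _, responses = study_survey
    design = dw.build_design(
        responses, states=[s.state_id for s in fixture_catalog])
    return dw.fit_probit(design)


def true_dw_map(catalog):
    return {s.state_id: s.true_dw for s in catalog}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
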