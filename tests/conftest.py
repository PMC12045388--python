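import logging

import numpy as np
import pytest

from ttwcausal.cohort import (
    Covariate,
    LinearModel,
    SimulationScenario,
    confounded_scenario,
    generate_cohort,
)

logging.getLogger("ttwcausal").setLevel(logging.ERROR)


def make_scenario(**overrides) -> SimulationScenario:
    """A tiny fully-observed two-covariate scenario for unit tests."""
    base = dict(
        n_records=500,
        seed=0,
        program_mix=(0.3, 0.5, 0.2),
        rfc_mix=(0.5, 0.4, 0.1),
        covariate_spec=(
            Covariate("severity", "binary", 0.4),
            Covariate("region", "categorical", (0.3, 0.5, 0.2), levels=("midwest", "south", "west")),
        ),
        propensity=LinearModel(-1.0, {"severity": 0.8}),
        outcome=LinearModel(-1.2, {"severity": 0.9, "region": {"south": -0.4}}),
        true_treatment_logor=np.log(2.0),
        rfc_structural_missingness=False,
    )
    base.update(overrides)
    return SimulationScenario(**base)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = generate_cohort(make_scenario(n_records=800, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def confounded_cohort():
    scenario = confounded_scenario(n_records=4000, seed=5, true_treatment_logor=np.log(2.0))
    cohort, truth = generate_cohort(scenario)
    return scenario, cohort, truth
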