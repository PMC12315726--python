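import numpy as np
import pytest

import netsift as ns


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong 12-node planted decline in a 30-node cohort (fast unit fixture)."""
    spec = ns.CohortSpec(
        n_subjects=200,
        n_nodes=30,
        planted=[ns.PlantedSubnetworkSpec(nodes=range(12), beta_age=-0.01)],
        noise_sd=0.3,
        seed=17,
    )
    stack, subjects, truth = ns.generate_cohort(spec)
    return stack, subjects, truth


@pytest.fixture(scope="session")
def null_cohort():
    spec = ns.CohortSpec(n_subjects=200, n_nodes=30, planted=[], noise_sd=0.3, seed=23)
    stack, subjects, truth = ns.generate_cohort(spec)
    return stack, subjects, truth


@pytest.fixture(scope="session")
def planted_fits(planted_cohort):
    stack, subjects, _ = planted_cohort
    return ns.fit_edges(stack, subjects)


@pytest.fixture(scope="session")
def null_fits(null_cohort):
    stack, subjects, _ = null_cohort
    return ns.fit_edges(stack, subjects)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
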