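import numpy as np
import pytest

from qfasakit import synthetic_data as sd


@pytest.fixture
def fa4():
    from qfasakit.signatures import FattyAcidSet

    return FattyAcidSet(["16:0", "18:1n9", "20:5n3", "22:6n3"])


@pytest.fixture
def small_scenario():
    """Five species, small specimen counts — fast but fully structured."""
    return sd.SyntheticScenario(
        n_specimens=(10, 8, 8, 10, 8),
        n_fatty_acids=12,
        n_predators=12,
        dispersion=0.10,
        predator_noise=0.02,
        seed=7,
    )


@pytest.fixture
def small_library(small_scenario):
    return sd.gen_prey_library(small_scenario)


@pytest.fixture
def small_cc(small_scenario, small_library):
    return sd.gen_calibration(
        small_scenario.n_fatty_acids,
        small_scenario.cc_spread,
        small_scenario.seed,
        fa_set=small_library.fa_set,
    )


@pytest.fixture
def small_cohort(small_scenario, small_library, small_cc):
    return sd.gen_predator_cohort(small_scenario, small_library, small_cc)


def random_simplex(rng, k):
    return rng.dirichlet(np.ones(k))
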