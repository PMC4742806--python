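import warnings

import numpy as np
import pytest

import reefocc
import reefocc.brt as brt_mod
import reefocc.synthetic as syn

#: desk-scale study conditions shared across the suite
N_LOC = 150
N_SP = 40
SEED = 11


@pytest.fixture(scope="session")
def correlates():
    return reefocc.generate_locations(N_LOC, seed=SEED)


@pytest.fixture(scope="session")
def traits(correlates):
    return reefocc.generate_species(N_SP, seed=SEED)


@pytest.fixture(scope="session")
def hulls(traits, correlates):
    return reefocc.generate_ranges(traits, correlates, seed=SEED)


@pytest.fixture(scope="session")
def params():
    return reefocc.default_params()


@pytest.fixture(scope="session")
def occurrence(traits, correlates, params, hulls):
    return reefocc.simulate_occurrence(traits, correlates, params, hulls, seed=SEED)


@pytest.fixture(scope="session")
def survey(occurrence, traits, params, correlates):
    sv = reefocc.simulate_surveys(occurrence, traits, params, n_replicates=4,
                                  seed=SEED, correlates=correlates)
    lists = syn.make_restricted_lists(sv, traits, seed=SEED)
    return reefocc.apply_missingness(sv, lists)


@pytest.fixture(scope="session")
def matrix(survey):
    return syn.pooled_presence(survey)


@pytest.fixture(scope="session")
def desk_settings():
    """Reduced boosting profile for fast unit tests."""
    return brt_mod.BRTSettings(max_trees=400, n_folds=5, seed=SEED)


@pytest.fixture(scope="session")
def brt_results(matrix, correlates, traits, desk_settings, hulls):
    """One shared within-range BRT run over all species."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return brt_mod.run_all_species(matrix, correlates, traits, desk_settings,
                                       hulls=hulls, within_range_only=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
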