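import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import pretermsig as ps


@pytest.fixture(scope="session")
def small_cohort_params():
    """A reduced cohort (8 term / 6 preterm, 20 min records) for fast tests."""
    return ps.CohortParams(n_term=8, n_preterm=6, duration=1200.0, seed=11)


@pytest.fixture(scope="session")
def small_window_sets(small_cohort_params):
    cohort = ps.generate_cohort(small_cohort_params)
    return [ps.window_disjoint(r, 10) for r in cohort]


@pytest.fixture(scope="session")
def small_feature_tables(small_window_sets):
    """(raw, lsdl) feature tables for the small cohort."""
    model = ps.search_optimal(small_window_sets)
    raw = ps.featurize_cohort(small_window_sets)
    dec = ps.featurize_cohort(small_window_sets, lsdl=model)
    return raw, dec, model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
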