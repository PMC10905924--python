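import numpy as np
import pytest

from colosim import datasets, default_params, make_cohort, simulate_cohort


@pytest.fixture(scope="session")
def life_table():
    return datasets.load_life_table()


@pytest.fixture(scope="session")
def benchmarks():
    return datasets.load_benchmarks()


@pytest.fixture(scope="session")
def calib_params():
    return datasets.load_calibrated_params()


@pytest.fixture(scope="session")
def reference_strategies():
    return datasets.load_reference_strategies()


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def small_cohort(life_table):
    return make_cohort(2000, 0.5, seed=7, life_table=life_table)


@pytest.fixture(scope="session")
def mid_cohort(life_table):
    return make_cohort(20_000, 0.5, seed=11, life_table=life_table)


@pytest.fixture(scope="session")
def mid_histories(mid_cohort, calib_params):
    return simulate_cohort(mid_cohort, calib_params)
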