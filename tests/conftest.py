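import pytest

from wbvm.cohort_prep import prepare_cohort
from wbvm.io_trend import year_tables
from wbvm.pipeline import RunConfig, run_comparator, run_valuation
from wbvm.synthetic_data import PopulationConfig, generate_population


@pytest.fixture(scope="session")
def small_panel():
    """An 800-member calibrated panel for cheap structural tests."""
    return generate_population(PopulationConfig(n_members=800, seed=7))


@pytest.fixture(scope="session")
def reference_panel():
    """A full-size (6,170-member) calibrated panel for marginal checks."""
    return generate_population(PopulationConfig(n_members=6170, seed=5))


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    cohort, _ = prepare_cohort(small_panel.frame)
    return cohort


@pytest.fixture(scope="session")
def small_years(small_cohort):
    return year_tables(small_cohort)


@pytest.fixture(scope="session")
def default_run():
    """One full valuation on the default calibrated population."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_valuation(RunConfig(seed=1))


@pytest.fixture(scope="session")
def default_comparator():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_comparator(RunConfig(seed=1))
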