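import pytest

from psadpath import (
    builtin_pathways,
    default_cohort_spec,
    fixture_cohort,
    outcome_table,
)


@pytest.fixture(scope="session")
def spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def fixture(spec):
    """The deterministic calibrated cohort (N=2055)."""
    return fixture_cohort(spec, seed=1)


@pytest.fixture(scope="session")
def pathways_by_name():
    return {p.name: p for p in builtin_pathways()}


@pytest.fixture(scope="session")
def outcomes(fixture):
    """Outcome rows for the four built-in pathways, keyed by name."""
    return {r.pathway: r for r in outcome_table(fixture, builtin_pathways())}
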