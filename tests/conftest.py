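import pytest

from cardiocohort import adjudicate_cohort, build_paper_fixture, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def adjudicated_fixture(fixture_cohort, registry):
    probands, variants = fixture_cohort
    return adjudicate_cohort(probands, variants, registry)
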