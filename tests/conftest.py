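import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")

from qconpath.qconcat_design import audit_junctions, recommended_exclusions
from qconpath.synthetic_data import fixture_concatamer, fixture_proteome


@pytest.fixture(scope="session")
def proteome():
    return fixture_proteome()


@pytest.fixture(scope="session")
def concatamer():
    return fixture_concatamer()


@pytest.fixture(scope="session")
def exclusions(concatamer):
    return recommended_exclusions(audit_junctions(concatamer, max_missed=1))
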