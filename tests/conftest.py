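import pytest
from hypothesis import settings

import pvsignal as pv

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

STUDY_PAIR = ("AVAPRITINIB", "Photosensitivity reaction")


@pytest.fixture(scope="session")
def fixture_universe():
    """The synthetic published-case-series universe plus its ground truth."""
    return pv.make_paper_like_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_cases(fixture_universe):
    dataset, _ = fixture_universe
    return pv.deduplicate(dataset).cases


@pytest.fixture(scope="session")
def study_queries():
    drug = pv.DrugQuery(names=frozenset({"AVAPRITINIB", "AYVAKIT"}),
                        roles=frozenset({"PS", "SS"}))
    event = pv.EventQuery(preferred_terms=frozenset({"Photosensitivity reaction"}))
    return drug, event


@pytest.fixture
def all_roles_query():
    return pv.DrugQuery(names=frozenset({"AVAPRITINIB"}),
                        roles=frozenset({"PS", "SS", "C", "I"}))
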