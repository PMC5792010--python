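import logging

import pytest

import raftkit as rk

logging.getLogger("raftkit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixture_dataset() -> rk.SurveyDataset:
    return rk.generate_paper_fixture()


@pytest.fixture(scope="session")
def litter_summary():
    return rk.load_litter_summary()


@pytest.fixture(scope="session")
def taxon_profiles():
    return rk.load_taxon_profiles()
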