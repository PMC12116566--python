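import numpy as np
import pandas as pd
import pytest

import pvfaers as pv
from pvfaers.cohort import DrugLexicon, MeddraStub
from pvfaers.synthetic_data import DERM_SOC, default_ai_config


@pytest.fixture(scope="session")
def config():
    return default_ai_config(n_reports=8000, seed=11)


@pytest.fixture(scope="session")
def bundle_and_truth(config):
    return pv.generate_bundle(config)


@pytest.fixture(scope="session")
def bundle(bundle_and_truth):
    return bundle_and_truth[0]


@pytest.fixture(scope="session")
def truth(bundle_and_truth):
    return bundle_and_truth[1]


@pytest.fixture(scope="session")
def dedup_bundle(bundle):
    kept, _ = pv.deduplicate(bundle.demo)
    return pv.restrict_bundle(bundle, set(kept["primaryid"].astype(int)))


@pytest.fixture(scope="session")
def lexicon(config):
    return DrugLexicon.from_config(config)


@pytest.fixture(scope="session")
def meddra(config):
    return MeddraStub.from_config(config)


@pytest.fixture
def soc_code():
    return DERM_SOC


def make_demo(rows):
    """Small demo table from (primaryid, caseid, fda_dt) triples."""
    return pd.DataFrame(
        {
            "primaryid": pd.array([r[0] for r in rows], dtype="Int64"),
            "caseid": pd.array([r[1] for r in rows], dtype="Int64"),
            "fda_dt": pd.array([r[2] for r in rows], dtype="Int64"),
        }
    )
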