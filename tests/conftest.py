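import logging

import pytest

from ehmine import synthetic_data as sd
from ehmine.classification import load_default_references, default_profiles


@pytest.fixture(autouse=True)
def _quiet_scan_warnings(caplog):
    # short-background "sequence shorter than profile" warnings are expected
    logging.getLogger("ehmine.mining").setLevel(logging.ERROR)
    yield
    logging.getLogger("ehmine.mining").setLevel(logging.NOTSET)


@pytest.fixture(scope="session")
def refs():
    return load_default_references()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_proteome():
    """A compact noiseless planted proteome shared across tests."""
    spec = sd.ProteomeSpec(
        counts={"LEH": 3, "abEH_Nterm": 4, "abEH_core": 4,
                "dehalogenase_like": 3, "background": 40},
        seed=11)
    db, manifest = sd.make_proteome(spec)
    return db, manifest
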