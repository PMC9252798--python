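import pytest

from biotx import (
    GuardProfile,
    load_default_endogenous_table,
    load_default_rulebase,
    parse_structure,
)
from biotx.evaluation import PROBE_PANEL


@pytest.fixture(scope="session")
def rulebase():
    return load_default_rulebase()


@pytest.fixture(scope="session")
def panel():
    """The 50-molecule probe panel, parsed once per session."""
    return [parse_structure(smiles) for smiles, _ in PROBE_PANEL]


@pytest.fixture(scope="session")
def guard():
    return GuardProfile.default()


@pytest.fixture(scope="session")
def endogenous_table():
    return load_default_endogenous_table()


@pytest.fixture(scope="session")
def acetaminophen():
    return parse_structure("CC(=O)Nc1ccc(O)cc1")


@pytest.fixture(scope="session")
def phenol():
    return parse_structure("Oc1ccccc1")
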