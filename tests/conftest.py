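import pytest

from neoscreen import synth


@pytest.fixture(scope="session")
def panel():
    return synth.make_panel(n_genes=12, seed=11)


@pytest.fixture(scope="session")
def kb_and_ledger(panel):
    return synth.make_kb(panel, seed=11)


@pytest.fixture(scope="session")
def kb(kb_and_ledger):
    return kb_and_ledger[0]


@pytest.fixture(scope="session")
def ledger(kb_and_ledger):
    return kb_and_ledger[1]
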