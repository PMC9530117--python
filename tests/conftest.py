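import pytest

from hoxswitch import build_motif, build_mpn_network


@pytest.fixture(scope="session")
def motif():
    return build_motif()


@pytest.fixture(scope="session")
def mpn_model():
    return build_mpn_network()
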