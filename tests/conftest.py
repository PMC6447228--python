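import pytest

from plastidrearr import make_reference


@pytest.fixture()
def small_ref():
    """18 kb quadripartite plastome: LSC 10 kb, IRs 2 kb, SSC 4 kb."""
    return make_reference(10000, 2000, 4000, seed=42)


@pytest.fixture()
def tiny_ref():
    """Smallest legal plastome (4 x 1 kb) for exhaustive checks."""
    return make_reference(1000, 1000, 1000, seed=7)
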