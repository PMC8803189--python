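import pytest
from hypothesis import settings

from attapriori.network import example_network, parse_network

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture
def net3():
    """The bundled 3-node worked-example network (f1=x3, f2=x1&!x3, f3=x1&!x2)."""
    return example_network()


@pytest.fixture
def names3(net3):
    return net3.node_names


@pytest.fixture
def identity_net():
    return parse_network("targets, factors\na, a\n")
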