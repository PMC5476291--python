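"""Shared fixtures: the synthetic core network, its reduction, and the
reference kinetic model."""

import pytest

from drumalg.examples import core_network, reduce_to_macroreactions
from drumalg.kinetics import KineticParameters, build_reduced_model, reference_model


@pytest.fixture(scope="session")
def core_net():
    network, assignment, exchange = core_network()
    return network, assignment, exchange


@pytest.fixture(scope="session")
def macroreactions(core_net):
    network, assignment, exchange = core_net
    return reduce_to_macroreactions(network, assignment, exchange)


@pytest.fixture(scope="session")
def pipeline_model(macroreactions):
    return build_reduced_model(macroreactions)


@pytest.fixture(scope="session")
def model():
    return reference_model()


@pytest.fixture(scope="session")
def params():
    return KineticParameters()
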