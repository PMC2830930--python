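import pytest

from xenoflux.fixtures import (
    CATECHOL_ROUTE_CHAIN,
    KNOWN_ROUTE_CHAIN,
    default_media,
    find_route,
    make_toy_model,
    make_toy_rules_and_registry,
)
from xenoflux.model import apply_media
from xenoflux.rules import expand_network


@pytest.fixture(scope="session")
def rules_registry_seed():
    return make_toy_rules_and_registry()


@pytest.fixture(scope="session")
def full_network(rules_registry_seed):
    """The complete 10-generation expansion from 1,2,4-TCB."""
    rules, _, seed = rules_registry_seed
    return expand_network([seed], rules, 10)


@pytest.fixture(scope="session")
def known_route(full_network):
    return find_route(full_network, KNOWN_ROUTE_CHAIN)


@pytest.fixture(scope="session")
def catechol_route(full_network):
    return find_route(full_network, CATECHOL_ROUTE_CHAIN)


@pytest.fixture(scope="session")
def toy_fixture():
    return make_toy_model()


@pytest.fixture()
def toy_model(toy_fixture):
    """Toy model with the minimal glucose medium applied (fresh copy)."""
    return apply_media(toy_fixture.model, default_media(toy_fixture.model))
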