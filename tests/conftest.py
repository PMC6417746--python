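import pytest

from twocpt import (
    FORWARD_COUPLED,
    MSO_SPEC,
    STRONGLY_COUPLED,
    WEAKLY_COUPLED,
    build_two_compartment_params,
)
from twocpt.protocols import find_gna_ref

NAMED_MODELS = {
    "weak": WEAKLY_COUPLED,
    "forward": FORWARD_COUPLED,
    "strong": STRONGLY_COUPLED,
}


@pytest.fixture(scope="session")
def spec():
    return MSO_SPEC


@pytest.fixture(scope="session")
def named_params(spec):
    """Passive parameter sets of the three named coupling configurations."""
    return {k: build_two_compartment_params(spec, cc) for k, cc in NAMED_MODELS.items()}


@pytest.fixture(scope="session")
def gna_refs(spec):
    """Reference sodium conductances, computed once and shared across tests."""
    return {k: find_gna_ref(spec, cc) for k, cc in NAMED_MODELS.items()}
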