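import pytest

from rsmpso.design import reference_design, reference_factors
from rsmpso.registry import RESPONSES, VARIETIES, registry_surfaces


@pytest.fixture(scope="session")
def factors():
    return reference_factors()


@pytest.fixture(scope="session")
def design13():
    return reference_design()


@pytest.fixture(scope="session")
def all_surfaces():
    return registry_surfaces()


@pytest.fixture(scope="session")
def variety_response_pairs():
    return [(v, r) for v in VARIETIES for r in RESPONSES]
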