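import pytest
from hypothesis import HealthCheck, settings

import vdwqdo

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return vdwqdo.load_element_table()


@pytest.fixture(scope="session")
def ne_params(table):
    return vdwqdo.qdo_parameters(table["Ne"])


@pytest.fixture(scope="session")
def sr_params(table):
    sr = table["Sr"]
    return vdwqdo.qdo_parameters(sr, damped=True, r_e_override=sr.re_ref)


@pytest.fixture(scope="session")
def noble_atoms(table):
    return [table[el] for el in vdwqdo.NOBLE_GAS_ELEMENTS]
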