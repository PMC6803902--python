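import hypothesis
import pytest

from cdspme.defaults import default_compounds, default_vial
from cdspme.synthetic_data import default_binding_constants

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def vial():
    return default_vial()


@pytest.fixture(scope="session")
def kb_defaults():
    return default_binding_constants()


@pytest.fixture(scope="session")
def compounds(kb_defaults):
    return default_compounds(kb=kb_defaults)


@pytest.fixture(scope="session")
def compounds_no_binding():
    return default_compounds()
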