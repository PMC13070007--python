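import pytest
from hypothesis import settings

import slisy

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def parent74():
    """Synthetic parent scFv with 74 labelled CDR sites (reference configuration)."""
    return slisy.example_parent()


@pytest.fixture(scope="session")
def design74(parent74):
    return slisy.build_library(1, parent74)


@pytest.fixture(scope="session")
def toy8():
    """Small 8-site design for fast read-level tests."""
    return slisy.toy_design(n_sites=8)
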