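import pytest

from csfbarrier.reibergram import load_default_families, load_default_variation_grid
from csfbarrier.steady_state import load_default_molecules


@pytest.fixture(scope="session")
def families():
    return load_default_families()


@pytest.fixture(scope="session")
def variation_grid():
    return load_default_variation_grid()


@pytest.fixture(scope="session")
def molecules():
    return load_default_molecules()
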