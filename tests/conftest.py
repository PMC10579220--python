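import pytest

from scsol import load_published_params, load_sitagliptin


@pytest.fixture(scope="session")
def sitagliptin():
    """The packaged 28-point sitagliptin phosphate / scCO2 dataset."""
    return load_sitagliptin()


@pytest.fixture(scope="session")
def published():
    """Published per-model fitted parameters and metrics."""
    return load_published_params()
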