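import numpy as np
import pytest

from tightbind import ATPDF_ACTINONIN, KineticScheme, MichaelisParams


@pytest.fixture
def atpdf() -> KineticScheme:
    """Reference scheme: plant deformylase / actinonin rate constants."""
    return ATPDF_ACTINONIN


@pytest.fixture
def mm() -> MichaelisParams:
    return MichaelisParams(kcat=37.0, Km=1e-3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
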