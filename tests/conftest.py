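import numpy as np
import pytest

from smnd.synthetic import OligomerFieldConfig


@pytest.fixture(scope="session")
def nuisance():
    """Canonical imaging conditions shared by the fitting tests.

    Dilute field (5 complexes/µm² over 20×20 µm ⇒ ~2000 complexes; pinned to
    3000 for the fitting tests), 5 nm subunit spacing, 60% detection
    efficiency, 10 nm localization precision, merged blinks, sparse
    background.
    """
    return OligomerFieldConfig(n_complexes=3000)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
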