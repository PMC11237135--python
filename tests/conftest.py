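import numpy as np
import pytest


@pytest.fixture
def fit_grid() -> np.ndarray:
    """Standard 2.5-50 Hz analysis grid at the 0.5 Hz resolution of 2-s epochs."""
    return np.arange(2.5, 50.0001, 0.5)


@pytest.fixture
def wide_grid() -> np.ndarray:
    """Grid covering 0.5-100 Hz, wider than the analysis range."""
    return np.arange(0.5, 100.0001, 0.5)
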