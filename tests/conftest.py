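import numpy as np
import pytest

from scamp import FractionSet, FractionSpectrum, Peak


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_fraction_set():
    """Three fractions, two compounds (one shared across fractions 1-2)."""
    return FractionSet([
        FractionSpectrum(1, [Peak(301.03538, 1000.0, 50.0),
                             Peak(400.1000, 200.0, 10.0)]),
        FractionSpectrum(2, [Peak(301.03540, 500.0, 25.0)]),
        FractionSpectrum(3, [Peak(450.2000, 80.0, 8.0)]),
    ])
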