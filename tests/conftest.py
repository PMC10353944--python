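import numpy as np
import pytest

from nichemech.fret import CalibrationCurve


@pytest.fixture
def cal():
    """Synthetic 6-node calibration: 0 pN -> 0.90 ... 10 pN -> 0.15."""
    return CalibrationCurve.default_synthetic()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
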