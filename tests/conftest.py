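import numpy as np
import pytest

from casensor import Chelator, SequentialBindingModel


@pytest.fixture
def chelator():
    """Br2-BAPTA-like reporter: Kd 2.3 uM, absorbance drops on binding."""
    return Chelator(kd=2.3e-6, a_free=0.55, a_bound=0.15)


@pytest.fixture
def n104h_model():
    """Three-site macroscopic model with the low-affinity variant's constants."""
    return SequentialBindingModel([5.92, 4.70, 4.23])


@pytest.fixture
def wt_model():
    return SequentialBindingModel([7.07, 5.55])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
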