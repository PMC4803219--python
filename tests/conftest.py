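import numpy as np
import pytest

from pulmomech.synthgen import LungModelParams, ManeuverSpec


@pytest.fixture
def maneuver():
    """Short maneuver (4 breaths of pre-ventilation) for fast tests."""
    return ManeuverSpec(VT=0.30, n_breaths_before_occlusion=4,
                        cannula_k1=0.3, cannula_k2=0.02)


@pytest.fixture
def wt_params():
    """Adult wild-type-like lung: Est 22.4 cmH2O/ml, purely elastic."""
    return LungModelParams(Est_true=22.4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
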