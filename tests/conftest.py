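import numpy as np
import pytest

from lumigrowth import ConversionConstants, ModelParameters

#: Published typical population values used throughout the tests.
TYPICAL_A = 0.399           # day^-1
TYPICAL_K = 4.35e9          # photons/sec
TYPICAL_LAM = 2.25
CV_A, CV_K, CV_LAM = 31.1, 55.3, 10.0
RSE_A = 7.02
PHOTONS_PER_CELL = 88.4
INJECTED_CELLS = 1.5e5
P0_SIGNAL = INJECTED_CELLS * PHOTONS_PER_CELL  # 1.326e7 photons/sec


@pytest.fixture
def typical_params() -> ModelParameters:
    return ModelParameters(a=TYPICAL_A, K=TYPICAL_K, P0=P0_SIGNAL, lam=TYPICAL_LAM)


@pytest.fixture
def conversion() -> ConversionConstants:
    return ConversionConstants()
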