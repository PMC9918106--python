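import numpy as np
import pytest

from dermspec.detection_eval import ExtendedConfusionMatrix
from dermspec.fixtures import make_calibration_set
from dermspec.reconstruction import fit_reconstruction_model
from dermspec.spectral_model import load_cmf_1931_2deg, load_illuminant_d65

CLASS_LABELS = ["BCC", "SCC", "SK"]

# Published confusion matrices used as evaluation inputs throughout the
# suite (rows: predicted BCC/SCC/SK/background-FN; columns: true
# BCC/SCC/SK/background-FP).
RGB_MATRIX = np.array(
    [
        [133, 7, 8, 45],
        [6, 66, 0, 27],
        [6, 1, 102, 54],
        [23, 16, 16, 0],
    ]
)
HSI_MATRIX = np.array(
    [
        [102, 4, 19, 74],
        [17, 72, 0, 10],
        [6, 0, 100, 55],
        [43, 14, 7, 0],
    ]
)


@pytest.fixture(scope="session")
def illuminant():
    return load_illuminant_d65()


@pytest.fixture(scope="session")
def cmf():
    return load_cmf_1931_2deg()


@pytest.fixture(scope="session")
def calibration_spectra():
    return make_calibration_set(24, seed=1134)


@pytest.fixture(scope="session")
def model(calibration_spectra, illuminant, cmf):
    return fit_reconstruction_model(calibration_spectra, illuminant, cmf, k=6)


@pytest.fixture
def rgb_matrix():
    return ExtendedConfusionMatrix(RGB_MATRIX.copy(), list(CLASS_LABELS))


@pytest.fixture
def hsi_matrix():
    return ExtendedConfusionMatrix(HSI_MATRIX.copy(), list(CLASS_LABELS))
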