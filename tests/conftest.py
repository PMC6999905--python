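import numpy as np
import pytest

from nof1serial.fixtures import DISCOUNTING_PATIENT, FIBROMYALGIA_PATIENTS, get_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def patient_1390():
    return DISCOUNTING_PATIENT


@pytest.fixture
def patient_18():
    return get_fixture("patient_18")


@pytest.fixture(params=[f.name for f in FIBROMYALGIA_PATIENTS])
def fibro_patient(request):
    return get_fixture(request.param)
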