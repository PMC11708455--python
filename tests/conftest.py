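import numpy as np
import pytest

from pwave.synthetic_ecg import (
    NoiseConfig, default_morphology, generate_record, load_calibration,
    make_patient_template,
)

FS = 1000.0


@pytest.fixture(scope="session")
def default_template():
    return make_patient_template(default_morphology(), FS)


@pytest.fixture(scope="session")
def noiseless_record(default_template):
    return generate_record(default_template, 60.0, NoiseConfig.silent(), seed=0)


@pytest.fixture(scope="session")
def noisy_record(default_template):
    return generate_record(default_template, 60.0, NoiseConfig(), seed=7)


@pytest.fixture(scope="session")
def calibration():
    return load_calibration()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)
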