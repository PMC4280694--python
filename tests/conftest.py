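import pytest
from hypothesis import HealthCheck, settings

import cardiotal as ct
from cardiotal.protocol import (ProtocolSpec, calibrate_pulmonary_hypertension,
                                run_course_protocol, run_steady)

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")


@pytest.fixture(scope="session")
def normal_preset():
    return ct.normal_preset()


@pytest.fixture(scope="session")
def normal_steady(normal_preset):
    """(result, summary, cycles) of the normal preset at dt=1e-4 s."""
    return run_steady(normal_preset)


@pytest.fixture(scope="session")
def calibrated_patient(normal_preset):
    patient, log = calibrate_pulmonary_hypertension(normal_preset)
    return patient, log


@pytest.fixture(scope="session")
def protocol_table(calibrated_patient):
    """The full 18-run course protocol on the calibrated patient."""
    patient, _ = calibrated_patient
    return run_course_protocol(patient, ProtocolSpec())


def relative_difference(a, b):
    return abs(a - b) / max(abs(a), abs(b), 1e-12)
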