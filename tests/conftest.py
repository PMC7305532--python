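import pytest
from hypothesis import HealthCheck, settings

from orthoforce import CorrectionFactorModel, builtin_table1, printed_coefficients

settings.register_profile(
    "repro", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture(scope="session")
def reference_model():
    """The packaged study under its original calibration conventions."""
    return CorrectionFactorModel.reference_study()


@pytest.fixture(scope="session")
def measured_results(reference_model):
    return reference_model.fit(base_mode="measured")


@pytest.fixture(scope="session")
def fitted_results(reference_model):
    return reference_model.fit(base_mode="fitted")


@pytest.fixture(scope="session")
def printed():
    return printed_coefficients()
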