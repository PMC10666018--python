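import pytest

from msfit.catalog import load_catalog
from msfit.synthetic import GeneratorParams, generate_calibration_stream, generate_template


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def hip_params():
    return GeneratorParams(exercise_id="one_leg_circle_1", n_reps=5)


@pytest.fixture(scope="session")
def hip_template_stream(hip_params):
    return generate_template(hip_params)


@pytest.fixture(scope="session")
def knee_params():
    return GeneratorParams(exercise_id="single_leg_extension_1", n_reps=5)


@pytest.fixture(scope="session")
def knee_template_stream(knee_params):
    return generate_template(knee_params)


@pytest.fixture(scope="session")
def calibration_stream():
    return generate_calibration_stream(duration_s=6.0, distance_m=2.5)
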