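import pytest

from wormassay import gradient


@pytest.fixture(scope="session")
def plate():
    return gradient.PlateModel()


@pytest.fixture(scope="session")
def standard_schedule():
    return gradient.standard_drop_schedule()


@pytest.fixture(scope="session")
def standard_field(standard_schedule, plate):
    return gradient.predict_field(standard_schedule, plate, grid_spacing_mm=0.5)
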