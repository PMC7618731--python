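import pytest

from fibremech import FibreModel, Instrument


@pytest.fixture
def instrument() -> Instrument:
    return Instrument()


@pytest.fixture
def fibre_model() -> FibreModel:
    return FibreModel()
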