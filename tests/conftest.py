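import pytest

from bhtreesim import RandomStream, SimConfig


@pytest.fixture
def stream():
    """Fresh deterministic stream per test."""
    return RandomStream(20240917)


@pytest.fixture
def delta_symmetric_config():
    """Fixed waiting times: speciate after 2, go extinct after 2.5 (doubling)."""
    return SimConfig(waitsp="const(2)", waitext="const(2.5)", mode="symmetric")


@pytest.fixture
def delta_asymmetric_config():
    """Same delta clocks under budding speciation (single surviving line)."""
    return SimConfig(waitsp="const(2)", waitext="const(2.5)", mode="asymmetric")
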