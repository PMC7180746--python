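import pytest

from nadex import ExtractionSystem
from nadex.synthetic_data import default_system, default_true_params


@pytest.fixture
def system() -> ExtractionSystem:
    """The study maceration system: 0.01 g BAS, 10 mL solvent, 25 C."""
    return default_system()


@pytest.fixture
def true_params():
    """Generator truth with the optimum at epsilon* = 45."""
    return default_true_params()
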