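import pytest

from cvlocus import QuantalParams
from cvlocus.simulate import ExperimentDesign, default_ltd_scenario


@pytest.fixture
def base_params() -> QuantalParams:
    """Reference baseline release parameters: n=5, p=0.55, q=0.35 mV, 0.1 mV noise."""
    return QuantalParams(n_sites=5, p_release=0.55, q_amp=0.35, sd_background=0.1)


@pytest.fixture
def ltd_scenario():
    """Presynaptic LTD: p drops 0.55 -> 0.4 at induction, q fixed."""
    return default_ltd_scenario()


@pytest.fixture
def design() -> ExperimentDesign:
    """60 baseline / 240 post sweeps at 10-s inter-stimulus interval."""
    return ExperimentDesign()
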