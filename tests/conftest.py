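import numpy as np
import pytest

from dpoaewave import PropagationOptions, WaveInterferenceModel, generate_frequency_response
from dpoaewave.reproduce import reproduce_quantities
from dpoaewave.synthetic import APICAL_BM


@pytest.fixture(scope="session")
def apical_response():
    """Default apical response on the measured-convention grid (with middle ear)."""
    return generate_frequency_response(APICAL_BM)


@pytest.fixture(scope="session")
def apical_fit():
    """Full apical ratio/level sweep with slow-wave, fast-wave, zero-phase and
    velocity-weighting variants sharing the transducer simulations."""
    model = WaveInterferenceModel.from_profile()
    return model.fit(
        f2=9000.0,
        levels=(40.0, 50.0, 60.0, 70.0, 75.0),
        variants=[
            PropagationOptions(mode="fast_wave"),
            PropagationOptions(mode="fast_wave", zero_phase_control=True),
            PropagationOptions(weighting="velocity"),
        ],
    )


@pytest.fixture(scope="session")
def reproduced():
    """Full end-to-end reproduction of the headline quantities."""
    return reproduce_quantities(seed=0)
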