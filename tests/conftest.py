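import numpy as np
import pytest

from doxopbpk import presets
from doxopbpk.population import representative_subject


@pytest.fixture(scope="session")
def training_subject():
    """Population-mean subject of the training-trial demographics."""
    return representative_subject(presets.trial_population("training_bolus"))


@pytest.fixture(scope="session")
def training_regimen():
    return presets.trial_regimen("training_bolus")


@pytest.fixture(scope="session")
def coarse_grid():
    """Fast grid for engine tests that do not probe the 2-min infusion peak."""
    return np.linspace(0.0, 72.0, 600)
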