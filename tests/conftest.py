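import warnings

import numpy as np
import pytest

from activeflicker import synthetic as syn
from activeflicker.params import MembraneParams

warnings.filterwarnings("ignore", message="vertex acceptance")


@pytest.fixture(scope="session")
def fast_membrane():
    """Small vesicle whose relaxation times are short enough that a few
    minutes of simulated recording hold thousands of correlation times."""
    return MembraneParams(kappa=13.4, sigma=0.0, R0=5.0)


@pytest.fixture(scope="session")
def active_record():
    """Default active preset, 10-minute recording."""
    return syn.active_preset(seed=11, n_steps=3000, dt=0.2)


@pytest.fixture(scope="session")
def passive_record():
    """Egg-PC-like passive vesicle: the measured tension of taut GUVs
    (~1e-7 N/m) keeps the mode relaxation times well below seconds, so
    pooled deformation windows mix many configurations (the regime in
    which passive GUVs look Gaussian at every averaging time)."""
    return syn.passive_preset(seed=7, n_steps=5000, dt=0.05, sigma=1.0e-7)
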