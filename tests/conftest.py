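import warnings

import numpy as np
import pytest

from oligopath.equilibrium import DEFAULT_PARAMS, KINETIC_FIT_PARAMS
from oligopath.synthetic import SyntheticSpec


@pytest.fixture
def default_params():
    """Titration-derived Kds: dimer 50 uM, hexamer 10e-9 M^2."""
    return DEFAULT_PARAMS


@pytest.fixture
def kinetic_params():
    """Kds with the hexamer affinity from the kinetic global fit."""
    return KINETIC_FIT_PARAMS


@pytest.fixture
def quiet_integrations():
    """Silence the intended top-of-ladder warnings in corpus-scale runs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def small_spec():
    """Noise-free study conditions for fast deterministic checks."""
    return SyntheticSpec(seed=0, sigma=0.0, n_replicates=1)
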