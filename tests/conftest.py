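import warnings

import numpy as np
import pytest

from inhibpipe import EphysGenConfig, ImagingGenConfig


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    """Mixed-model REML fits on tiny synthetic tables warn about boundary
    variance estimates; those are expected and irrelevant to the checks."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                module="statsmodels")
        yield


@pytest.fixture
def noiseless_ipsc_config() -> EphysGenConfig:
    """Electrical-iML-like double-pulse config with zero noise."""
    return EphysGenConfig(
        A1_true=372.5, ppr_true=0.84, rise_20_80_true=4.92,
        tau_decay_true=79.86, noise_sd=0.0, n_sweeps=1, seed=0,
    )


@pytest.fixture
def small_stack_config() -> ImagingGenConfig:
    """Small sparse stack that renders and analyzes in about a second."""
    return ImagingGenConfig(
        stack_size_um=(20.0, 20.0, 5.0), density_vgat=0.14,
        frac_double=0.5, seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
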