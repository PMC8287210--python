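import logging

import numpy as np
import pytest

from gratiomap.pipeline import AnalysisConfig
from gratiomap.synthetic_phantom import PhantomConfig

logging.disable(logging.WARNING)


@pytest.fixture
def rng():
    return np.random.default_rng(20210705)


def make_config(**overrides) -> PhantomConfig:
    return PhantomConfig(**overrides)


def noiseless_kwargs(**extra) -> dict:
    """Phantom settings with every stochastic corruption switched off."""
    kw = dict(
        mtsat_noise_sd=0.0,
        nu_icvf_noise_sd=0.0,
        nu_iso_noise_sd=0.0,
        ceiling_enabled=False,
        n_subjects=2,
    )
    kw.update(extra)
    return kw


@pytest.fixture
def noiseless_nominal_config() -> PhantomConfig:
    """No noise, nominal transmit field everywhere, no surrogate error."""
    return make_config(**noiseless_kwargs(b1_amplitude=0.0, un_error_amplitude=0.0))


@pytest.fixture
def noiseless_biased_config() -> PhantomConfig:
    """No noise, but a +/-20% transmit-field inhomogeneity."""
    return make_config(**noiseless_kwargs(b1_amplitude=0.2, un_error_amplitude=0.0, seed=7))


@pytest.fixture
def default_analysis_config() -> AnalysisConfig:
    return AnalysisConfig(seed=0)
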