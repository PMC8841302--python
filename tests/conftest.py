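import numpy as np
import pytest

from megpac import SimulationConfig, simulate_subject


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation: short epoch, reduced rate, few trials."""
    return SimulationConfig(
        n_responder=4, n_nonresponder=4, n_hc=3,
        n_trials=10, epoch_len_s=0.5, pre_stim_s=0.3, fs=300.0,
    )


@pytest.fixture(scope="session")
def coupled_subject(small_config):
    """One strongly coupled subject at desk scale."""
    roi, rec = simulate_subject(small_config, "responder", rng=7, kappa=0.8)
    return roi, rec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
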