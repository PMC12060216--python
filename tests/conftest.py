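import numpy as np
import pytest

import nirstates as ns


@pytest.fixture(scope="session")
def design():
    return ns.TaskDesign()


@pytest.fixture(scope="session")
def montage():
    return ns.default_montage()


@pytest.fixture(scope="session")
def clean_params():
    """Generator settings with every noise and artifact source off."""
    return ns.SimulationParams(
        white_sd=0.0,
        latent_sd=0.0,
        mayer_amp=0.0,
        resp_amp=0.0,
        cardiac_amp=0.0,
        drift_slope=0.0,
        spike_rate_per_min=0.0,
        shift_rate_per_session=0.0,
        beta_subject_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_subject(clean_params, design):
    rec, truth = ns.simulate_subject(clean_params, design, "HC", seed=11)
    return rec, truth


@pytest.fixture(scope="session")
def default_subject(design):
    rec, truth = ns.simulate_subject(ns.SimulationParams(), design, "PD+FOG", seed=7)
    return rec, truth
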