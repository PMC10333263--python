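"""Shared fixtures: frozen training scenarios and desk-scale posterior runs.

The MCMC fixtures run the real training pipeline at reduced chain lengths
(scale_factor 0.01-0.02, i.e. 15,000-30,000 steps per chain instead of the
full-scale 1.5 million) so the whole suite fits a desktop budget.  They are
session-scoped and shared across test modules.
"""

import numpy as np
import pytest

from predband.inference import MCMCConfig, run_training
from predband.models import get_model
from predband.synthetic import make_training_scenario


@pytest.fixture(scope="session")
def cascade_scenario():
    return make_training_scenario("cascade_train")


@pytest.fixture(scope="session")
def short_on_scenario():
    return make_training_scenario("cascade_train_short_on")


def _train(scenario, variables, model=None, scale=0.02, seed=202, **kwargs):
    gen_model, protocol, measurements = scenario
    model = gen_model if model is None else model
    config = MCMCConfig(seed=seed, scale_factor=scale, **kwargs)
    return run_training(model, measurements, variables, config=config, protocol=protocol)


@pytest.fixture(scope="session")
def k4_posterior(cascade_scenario):
    """Nominal cascade trained on K4 only."""
    return _train(cascade_scenario, ["K4"], scale=0.05, seed=202)


@pytest.fixture(scope="session")
def k2k4_posterior(cascade_scenario):
    """Nominal cascade trained on K2 and K4."""
    return _train(cascade_scenario, ["K2", "K4"], scale=0.02, seed=203)


@pytest.fixture(scope="session")
def all_posterior(cascade_scenario):
    """Nominal cascade trained on all four variables."""
    return _train(cascade_scenario, ["K1", "K2", "K3", "K4"], scale=0.1, seed=204)


@pytest.fixture(scope="session")
def relaxed_posterior(cascade_scenario):
    """Relaxed cascade (f1, f2, f3 all free) trained on K4 only."""
    return _train(cascade_scenario, ["K4"], model=get_model("relaxed"), scale=0.02, seed=206)


@pytest.fixture(scope="session")
def simplified_posterior(cascade_scenario):
    """Two-step simplified cascade trained on nominal K4 data."""
    return _train(cascade_scenario, ["K4"], model=get_model("simplified"), scale=0.01, seed=207)


@pytest.fixture(scope="session")
def short_on_posterior(short_on_scenario):
    """Nominal cascade trained on K4 from the inadequate 1-h 'on' protocol."""
    return _train(short_on_scenario, ["K4"], scale=0.01, seed=208)
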