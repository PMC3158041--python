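"""Shared desk-scale fixtures.

All data are generated programmatically from the frozen ground-truth model;
session scope keeps the expensive surrogate simulations to one run.
"""

import numpy as np
import pytest

from cbmfit.model import ParameterVector, SimulationConfig
from cbmfit.morphology import Morphology
from cbmfit.stimuli import make_ramp, make_step
from cbmfit.surrogate import NoiseModel, generate, ground_truth_parameters


@pytest.fixture(scope="session")
def morphology():
    return Morphology()


@pytest.fixture(scope="session")
def soma_only():
    return Morphology(n_dend=0)


@pytest.fixture(scope="session")
def ground_truth():
    return ground_truth_parameters()


@pytest.fixture(scope="session")
def passive_params(ground_truth):
    zeros = {k: 0.0 for k in (
        "gbar_nat", "gbar_kd", "gbar_kp", "gbar_kv31",
        "gbar_ca", "gbar_sk", "gbar_ih", "gbar_im")}
    return ground_truth.with_values(**zeros)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def desk_config():
    """Coarser desk-scale integration used by the fitting fixtures."""
    return SimulationConfig(dt=0.1, settle_ms=100.0)


@pytest.fixture(scope="session")
def desk_battery():
    """Two suprathreshold 1 s steps and two 1 s ramps at desk resolution."""
    dt = 0.1
    return {
        "stepA": make_step(150.0, onset_s=0.1, duration_s=1.0, tail_s=0.05,
                           dt_ms=dt, name="stepA"),
        "stepB": make_step(200.0, onset_s=0.1, duration_s=1.0, tail_s=0.05,
                           dt_ms=dt, name="stepB"),
        "stepC": make_step(175.0, onset_s=0.1, duration_s=1.0, tail_s=0.05,
                           dt_ms=dt, name="stepC"),
        "stepD": make_step(225.0, onset_s=0.1, duration_s=1.0, tail_s=0.05,
                           dt_ms=dt, name="stepD"),
        "rampA": make_ramp(200.0, rise_s=1.0, onset_s=0.1, dt_ms=dt, name="rampA"),
        "rampB": make_ramp(250.0, rise_s=1.0, onset_s=0.1, dt_ms=dt, name="rampB"),
    }


@pytest.fixture(scope="session")
def desk_dataset(desk_battery, morphology, desk_config):
    """Surrogate recordings: 10 noisy repetitions of each desk stimulus."""
    return generate(battery=desk_battery, n_reps=10, noise=NoiseModel(),
                    seed=3, morphology=morphology, config=desk_config)


@pytest.fixture(scope="session")
def desk_targets(desk_dataset):
    return {n: desk_dataset.feature_targets(n) for n in desk_dataset.battery}


@pytest.fixture(scope="session")
def free_params():
    return ("gbar_nat", "gbar_kd", "gbar_kv31")
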