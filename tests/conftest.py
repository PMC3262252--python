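"""Shared fixtures: the demo clock pipeline is expensive, so orbit and
sensitivity objects are computed once per session and reused read-only."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clockbalance as cb

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def demo_model():
    return cb.build_demo("damped")


@pytest.fixture(scope="session")
def osc_model():
    return cb.build_demo("oscillatory")


@pytest.fixture(scope="session")
def protocol():
    return cb.LightProtocol(dawn=6.0, dusk=18.0, period=24.0)


@pytest.fixture(scope="session")
def demo_orbit(demo_model):
    return cb.find_entrained_orbit(demo_model)


@pytest.fixture(scope="session")
def demo_sens(demo_orbit):
    return cb.compute_sensitivities(demo_orbit, method="variational")


@pytest.fixture(scope="session")
def demo_sens_fd(demo_orbit):
    return cb.compute_sensitivities(demo_orbit, method="finite_difference")


@pytest.fixture(scope="session")
def pc_abs(demo_sens):
    return cb.principal_components(demo_sens, mode="absolute")


@pytest.fixture(scope="session")
def pc_rel(demo_sens):
    return cb.principal_components(demo_sens, mode="relative")


@pytest.fixture(scope="session")
def demo_k(demo_model):
    return {
        p: float(demo_model.param_values[demo_model.param_index(p)])
        for p in demo_model.temp_params
    }


@pytest.fixture(scope="session")
def balanced_light_model(demo_model, pc_rel):
    mod = cb.solve_light_balance(
        pc_rel, demo_model.light_params, fixed_c={"q2": 1.0}, r=2
    )
    return cb.apply_light_modification(demo_model, mod)


# allow plain-module imports (reference_tables) from the tests directory
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
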