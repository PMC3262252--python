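"""Bundled demo clocks and a generator of randomized test models.

The damped demo clock is a three-state negative-feedback loop (mRNA x1,
cytoplasmic protein x2, nuclear protein x3) with Hill repression of
transcription by the nuclear protein and three light entry points: light-
activated transcription (q1), light-enhanced cytoplasmic degradation (q2)
and light-enhanced nuclear import (q3).  With Hill exponent 2 the dark
system has a unique stable equilibrium, so the light-forced system has a
unique attracting 24 h orbit for every tested perturbation — the standing
assumption of the sensitivity framework.

The oscillatory variant raises the Hill exponent and lowers degradation so
the dark system self-oscillates; it exists to exercise free-running-period
analysis.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .arrhenius import ArrheniusParam
from .model import ClockModel, model_from_dict
from .orbit import TemperatureSchedule

import yaml

__all__ = ["build_demo", "random_instance", "demo_temperature_schedule"]

_FILES = {"damped": "demo_damped.yaml", "oscillatory": "demo_oscillatory.yaml"}


def build_demo(variant: str = "damped") -> ClockModel:
    """Load a bundled demo model: ``"damped"`` or ``"oscillatory"``."""
    try:
        fname = _FILES[variant]
    except KeyError:
        raise ValueError(f"unknown demo variant {variant!r}; choose from {sorted(_FILES)}")
    text = resources.files("clockbalance.data").joinpath(fname).read_text()
    return model_from_dict(yaml.safe_load(text))


def demo_temperature_schedule(
    model: ClockModel,
    energies: dict[str, float] | float = 50.0,
    T_day: float = 290.15,
    T_night: float = 285.15,
    T_ref: float = 288.15,
) -> TemperatureSchedule:
    """Arrhenius layer for the demo's temperature-sensitive parameters.

    Each parameter keeps its nominal value at the reference temperature
    (288.15 K) and is assigned the given activation energy (single value or
    per-parameter map; 50 kJ/mol placeholder by default).
    """
    if not model.temp_params:
        raise ValueError("model declares no temperature-sensitive parameters")
    if np.isscalar(energies):
        energies = {p: float(energies) for p in model.temp_params}
    params = {
        p: ArrheniusParam(
            energy=float(energies[p]),
            k_ref=float(model.param_values[model.param_index(p)]),
            T_ref=T_ref,
        )
        for p in model.temp_params
    }
    return TemperatureSchedule(params=params, T_day=T_day, T_night=T_night)


def random_instance(n_states: int = 3, n_light_params: int = 2, seed: int = 0) -> ClockModel:
    """Generate a random damped feedback-chain clock for property tests.

    The linear part is a production chain x1 -> x2 -> ... -> xn with
    diagonally dominant degradation, closed by Hill repression of x1 by the
    last state (exponent 2, hence damped); light enters ``n_light_params``
    terms, alternating additive drives ``+q theta`` and proportional drives
    ``-q theta x``.  Deterministic for a fixed seed.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    rng = np.random.default_rng(seed)
    names, values, eqs = [], [], []

    def add(name: str, value: float) -> str:
        names.append(name)
        values.append(float(value))
        return name

    add("n1", rng.uniform(0.6, 1.4))
    add("g1", rng.uniform(0.7, 1.3))
    add("hh", 2.0)
    for i in range(1, n_states + 1):
        add(f"m{i}", rng.uniform(0.25, 0.6))
        if i > 1:
            add(f"p{i}", rng.uniform(0.4, 0.9))
    feedback = f"x{n_states}"
    eqs.append(f"n1/(1 + ({feedback}/g1)**hh) - m1*x1")
    for i in range(2, n_states + 1):
        eqs.append(f"p{i}*x{i - 1} - m{i}*x{i}")

    light = []
    for ell in range(n_light_params):
        q = add(f"q{ell + 1}", rng.uniform(0.1, 0.4))
        light.append(q)
        target = int(rng.integers(0, n_states))
        if ell % 2 == 0:
            eqs[target] += f" + {q}*theta"
        else:
            eqs[target] += f" - {q}*theta*x{target + 1}"
    states = [f"x{i + 1}" for i in range(n_states)]
    return model_from_dict(
        {
            "states": states,
            "parameters": dict(zip(names, values)),
            "equations": eqs,
            "light_params": light,
            "temp_params": [f"m{i}" for i in range(1, n_states + 1)],
            "forcing_period": 24.0,
        }
    )
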