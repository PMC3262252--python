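"""Declarative forced ODE clock models and the light protocol.

A model is a set of state variables (mRNA / protein concentrations, nM), a
positive parameter vector ``k`` (time unit: hours), and one rate expression
per state written over the states, the parameters and the symbol ``theta``,
the light signal.  A designated subset of parameters (the *light parameters*)
enters the equations only in products with ``theta``; a second subset (the
*temperature parameters*) can be given Arrhenius temperature dependence.

Light fluctuations scale the light drive: the term ``k_j * theta(t)`` becomes
``k_j * alpha * theta(t)`` where ``alpha`` is the (daily) light intensity.  A
:class:`LightModification` regulates each light input so that the drive is
``k_j * (c_j * alpha + d_j) * theta(t)`` with ``c_j + d_j = 1``, which leaves
the mean drive unchanged while attenuating its dependence on ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp
import yaml

__all__ = [
    "ClockModel",
    "LightProtocol",
    "LightModification",
    "ModelDefinitionError",
    "light_value",
    "evaluate_rhs",
    "apply_light_modification",
    "load_model",
    "save_model",
]


class ModelDefinitionError(ValueError):
    """Raised when a model description is inconsistent or malformed."""


@dataclass(frozen=True)
class LightProtocol:
    """Periodic day/night light signal theta(t) in [0, 1].

    Parameters
    ----------
    dawn, dusk:
        Start and end of the lit interval, hours within the forcing cycle.
    period:
        Forcing period tau in hours (24 by default).
    mode:
        ``"square"`` for an exact 0/1 square wave, ``"smoothed"`` for
        logistic ramps of width ``width`` at dawn and dusk.
    width:
        Ramp width in hours (only used in smoothed mode).
    """

    dawn: float = 6.0
    dusk: float = 18.0
    period: float = 24.0
    mode: str = "square"
    width: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.dawn < self.period:
            raise ValueError(f"dawn must lie in [0, period); got {self.dawn}")
        if not self.dawn < self.dusk <= self.period:
            raise ValueError(f"dusk must lie in (dawn, period]; got {self.dusk}")
        if self.mode not in ("square", "smoothed"):
            raise ValueError(f"unknown light mode {self.mode!r}")
        if self.width < 0:
            raise ValueError("smoothing width must be >= 0")

    def is_day(self, t: float) -> bool:
        tm = t % self.period
        return self.dawn <= tm < self.dusk


def light_value(protocol: LightProtocol, t):
    """Evaluate theta(t); periodic with the protocol's period.

    Square mode returns exactly 0.0 or 1.0; smoothed mode multiplies
    logistic ramps centred at dawn and dusk.
    """
    tm = np.asarray(t) % protocol.period
    if protocol.mode == "square":
        out = np.where((tm >= protocol.dawn) & (tm < protocol.dusk), 1.0, 0.0)
        return float(out) if np.isscalar(t) else out
    w = max(protocol.width, 1e-12)
    # logistic ramps; the product stays within [0, 1] and is ~1 mid-day
    up = 1.0 / (1.0 + np.exp(-(tm - protocol.dawn) / w))
    down = 1.0 / (1.0 + np.exp(-(protocol.dusk - tm) / w))
    out = up * down
    return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class LightModification:
    """Per-light-parameter regulation weights c_j (d_j = 1 - c_j implied)."""

    c: dict[str, float]

    def c_vector(self, light_params: list[str]) -> np.ndarray:
        return np.array([self.c.get(name, 1.0) for name in light_params])

    def d_vector(self, light_params: list[str]) -> np.ndarray:
        return 1.0 - self.c_vector(light_params)


_ALLOWED_FUNCS = {
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
    "sin": sp.sin,
    "cos": sp.cos,
}


@dataclass(frozen=True)
class ClockModel:
    """A forced ODE model dx/dt = f(x, k, theta(t)).

    ``light_params`` lists the parameters multiplying the light signal;
    ``temp_params`` lists the parameters eligible for Arrhenius temperature
    dependence.  ``light_mod`` holds the regulation weights c_j (all 1 for
    the unmodified model, in which the light drive is ``k_j * alpha *
    theta``).
    """

    state_names: list[str]
    param_names: list[str]
    param_values: np.ndarray
    equations: list[str]
    light_params: list[str] = field(default_factory=list)
    temp_params: list[str] = field(default_factory=list)
    forcing_period: float = 24.0
    light_mod: LightModification | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "param_values", np.asarray(self.param_values, dtype=float))
        if len(self.state_names) < 1:
            raise ModelDefinitionError("model needs at least one state")
        if len(self.equations) != len(self.state_names):
            raise ModelDefinitionError("one rate expression per state required")
        if len(self.param_names) != len(self.param_values):
            raise ModelDefinitionError("parameter names/values length mismatch")
        if np.any(self.param_values <= 0):
            raise ModelDefinitionError("all parameter values must be positive")
        for sub in (self.light_params, self.temp_params):
            unknown = set(sub) - set(self.param_names)
            if unknown:
                raise ModelDefinitionError(f"unknown parameters in subset: {sorted(unknown)}")
        object.__setattr__(self, "_compiled", None)
        self.compiled  # compile eagerly: malformed expressions fail here

    # -- indexing helpers -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    @property
    def light_idx(self) -> np.ndarray:
        return np.array([self.param_index(n) for n in self.light_params], dtype=int)

    @property
    def temp_idx(self) -> np.ndarray:
        return np.array([self.param_index(n) for n in self.temp_params], dtype=int)

    # -- compilation ------------------------------------------------------
    @property
    def compiled(self) -> "CompiledModel":
        if self.__dict__.get("_compiled") is None:
            object.__setattr__(self, "_compiled", CompiledModel(self))
        return self.__dict__["_compiled"]

    def light_scale(self, alpha: float) -> np.ndarray:
        """Multiplier (c_j*alpha + d_j) for each light parameter, in order."""
        if self.light_mod is None:
            c = np.ones(len(self.light_params))
        else:
            c = self.light_mod.c_vector(self.light_params)
        return c * alpha + (1.0 - c)

    def effective_params(self, k: np.ndarray | None = None, alpha: float = 1.0) -> np.ndarray:
        """Parameter vector with the light drive scaled by (c*alpha + d).

        Valid because light parameters appear only in products with theta,
        so scaling the parameter is identical to scaling its theta-term.
        """
        keff = np.array(self.param_values if k is None else k, dtype=float)
        if len(self.light_params):
            keff[self.light_idx] = keff[self.light_idx] * self.light_scale(alpha)
        return keff


class CompiledModel:
    """Numeric callables (rhs, Jacobians) compiled from the expressions."""

    def __init__(self, model: ClockModel):
        xs = [sp.Symbol(s, real=True) for s in model.state_names]
        ks = [sp.Symbol(s, positive=True) for s in model.param_names]
        th = sp.Symbol("theta", nonnegative=True)
        ns: dict[str, object] = {s.name: s for s in xs + ks}
        if "theta" in ns:
            raise ModelDefinitionError("'theta' is reserved for the light signal")
        ns["theta"] = th
        ns.update(_ALLOWED_FUNCS)
        exprs = []
        allowed = set(xs) | set(ks) | {th}
        for eq in model.equations:
            try:
                e = sp.sympify(eq, locals=ns)
            except (sp.SympifyError, SyntaxError, TypeError) as err:
                raise ModelDefinitionError(f"cannot parse rate expression {eq!r}: {err}")
            extra = e.free_symbols - allowed
            if extra:
                raise ModelDefinitionError(
                    f"expression {eq!r} references unknown symbols {sorted(map(str, extra))}"
                )
            exprs.append(e)
        f = sp.Matrix(exprs)
        # light parameters must enter only through products with theta
        for name in model.light_params:
            q = ns[name]
            resid = f.diff(q).subs(th, 0)
            if any(sp.simplify(r) != 0 for r in resid):
                raise ModelDefinitionError(
                    f"light parameter {name!r} appears outside theta-modulated terms"
                )
        args = (tuple(xs), tuple(ks), th)
        self._rhs = sp.lambdify(args, list(f), "numpy")
        self._jx = sp.lambdify(args, f.jacobian(xs).tolist(), "numpy")
        self._jk = sp.lambdify(args, f.jacobian(ks).tolist(), "numpy")
        self.n = len(xs)
        self.s = len(ks)

    def rhs(self, x, k, theta: float) -> np.ndarray:
        return np.asarray(self._rhs(tuple(x), tuple(k), theta), dtype=float)

    def jac_x(self, x, k, theta: float) -> np.ndarray:
        return np.asarray(self._jx(tuple(x), tuple(k), theta), dtype=float)

    def jac_k(self, x, k, theta: float) -> np.ndarray:
        return np.asarray(self._jk(tuple(x), tuple(k), theta), dtype=float)


def evaluate_rhs(
    model: ClockModel,
    t: float,
    x,
    k: np.ndarray | None = None,
    alpha: float = 1.0,
    protocol: LightProtocol | None = None,
) -> np.ndarray:
    """Evaluate dx/dt at time ``t`` with light intensity ``alpha``.

    With ``alpha = 1`` and no modification this is the unmodified model.
    """
    protocol = protocol if protocol is not None else LightProtocol(period=model.forcing_period)
    theta = light_value(protocol, t)
    keff = model.effective_params(k, alpha)
    return model.compiled.rhs(np.asarray(x, dtype=float), keff, theta)


def apply_light_modification(model: ClockModel, mod: LightModification) -> ClockModel:
    """Return a copy of the model with regulated light inputs.

    The drive of light parameter ``k_j`` becomes ``k_j (c_j alpha + d_j)
    theta(t)`` with ``d_j = 1 - c_j``; at ``alpha = 1`` the modified and the
    original model coincide exactly.
    """
    unknown = set(mod.c) - set(model.light_params)
    if unknown:
        raise ModelDefinitionError(
            f"modification weights given for non-light parameters: {sorted(unknown)}"
        )
    modified = replace(model, light_mod=mod)
    # the compiled callables depend only on the expressions; share the cache
    object.__setattr__(modified, "_compiled", model.__dict__.get("_compiled"))
    return modified


# -- serialization --------------------------------------------------------

def model_to_dict(model: ClockModel) -> dict:
    d = {
        "states": list(model.state_names),
        "parameters": {n: float(v) for n, v in zip(model.param_names, model.param_values)},
        "equations": list(model.equations),
        "light_params": list(model.light_params),
        "temp_params": list(model.temp_params),
        "forcing_period": float(model.forcing_period),
    }
    if model.light_mod is not None:
        d["light_mod"] = {n: float(c) for n, c in model.light_mod.c.items()}
    return d


def model_from_dict(d: dict) -> ClockModel:
    params = d.get("parameters", {})
    mod = LightModification(c=dict(d["light_mod"])) if d.get("light_mod") else None
    return ClockModel(
        state_names=list(d["states"]),
        param_names=list(params.keys()),
        param_values=np.array(list(params.values()), dtype=float),
        equations=list(d["equations"]),
        light_params=list(d.get("light_params", [])),
        temp_params=list(d.get("temp_params", [])),
        forcing_period=float(d.get("forcing_period", 24.0)),
        light_mod=mod,
    )


def load_model(path) -> ClockModel:
    """Load a model from its YAML description file."""
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def save_model(model: ClockModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)
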