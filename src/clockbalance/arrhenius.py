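"""Arrhenius temperature dependence of rate parameters.

Rate constants are modelled as ``k(T) = A exp(-E/RT)`` with activation
energy ``E`` in kJ/mol and ``T`` in kelvin.  A parameter is specified either
by its prefactor ``A`` or, more conveniently, by a reference pair
``(k_ref, T_ref)``; the two are related by ``A = k_ref exp(E/(R T_ref))``.

Day/night forcing splits a temperature-sensitive parameter into a morning
and an evening term, ``k_j = k_j^D theta + k_j^N (1 - theta)``, evaluated at
the (possibly fluctuating) day and night temperatures.

Sign convention
---------------
Under the standard law, rates increase with temperature when ``E > 0``, and
the first-order Taylor coefficient about ``T`` is ``+k0 E / (R T^2)``.  Some
published day/night parameter tables follow the opposite convention, with
rates increasing toward the colder night temperature (equivalently, a Taylor
coefficient ``-k0 E / (R T^2)``); set ``increasing_with_temperature=False``
to reproduce such tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "ENERGY_BOUNDS",
    "ArrheniusParam",
    "DayNightParam",
    "arrhenius_value",
    "taylor_coefficients",
    "day_night_parameter",
]

#: Gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT = 8.314472e-3

#: Physiologically sensible activation-energy range, kJ mol^-1.
ENERGY_BOUNDS = (1.0, 150.0)


@dataclass(frozen=True)
class ArrheniusParam:
    """Arrhenius description of one rate parameter.

    Parameters
    ----------
    energy:
        Activation energy E, kJ/mol.  Values outside ``ENERGY_BOUNDS`` raise
        a warning (or an error with ``strict_bounds=True``).
    k_ref, T_ref:
        Reference rate value and the kelvin temperature at which it holds.
    increasing_with_temperature:
        Direction convention; see module docstring.
    """

    energy: float
    k_ref: float
    T_ref: float
    increasing_with_temperature: bool = True
    strict_bounds: bool = False

    def __post_init__(self) -> None:
        if self.k_ref <= 0:
            raise ValueError("reference rate must be positive")
        if self.T_ref <= 0:
            raise ValueError("reference temperature must be positive (kelvin)")
        lo, hi = ENERGY_BOUNDS
        if not lo <= self.energy <= hi:
            msg = (
                f"activation energy {self.energy} kJ/mol outside the "
                f"physiological range [{lo}, {hi}]"
            )
            if self.strict_bounds:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)

    @property
    def sign(self) -> float:
        return 1.0 if self.increasing_with_temperature else -1.0

    @property
    def prefactor(self) -> float:
        """A such that k(T) = A exp(-sign * E / (R T))."""
        return self.k_ref * np.exp(self.sign * self.energy / (GAS_CONSTANT * self.T_ref))


def arrhenius_value(p: ArrheniusParam, T) -> float | np.ndarray:
    """Rate value k(T) at kelvin temperature ``T``.

    Satisfies the ratio law ``k(T2)/k(T1) = exp(sign*(E/R)(1/T1 - 1/T2))``
    and recovers ``k_ref`` exactly at ``T_ref``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    E_over_R = p.energy / GAS_CONSTANT
    out = p.k_ref * np.exp(p.sign * E_over_R * (1.0 / p.T_ref - 1.0 / T))
    return float(out) if out.ndim == 0 else out


def taylor_coefficients(p: ArrheniusParam, T: float) -> tuple[float, float]:
    """First-order Taylor coefficients (k0, k1) of k about temperature ``T``.

    ``k0 = k(T)`` and ``k1 = dk/dT = sign * k0 * E / (R T^2)``, so that
    ``k(T + eps) ~= k0 + k1*eps`` with an O(eps^2) remainder.
    """
    k0 = arrhenius_value(p, T)
    k1 = p.sign * k0 * p.energy / (GAS_CONSTANT * T * T)
    return k0, k1


@dataclass(frozen=True)
class DayNightParam:
    """Day/night split of one temperature-sensitive parameter."""

    base: ArrheniusParam
    T_day: float
    T_night: float

    @property
    def k_day(self) -> float:
        return arrhenius_value(self.base, self.T_day)

    @property
    def k_night(self) -> float:
        return arrhenius_value(self.base, self.T_night)

    def taylor_day(self) -> tuple[float, float]:
        return taylor_coefficients(self.base, self.T_day)

    def taylor_night(self) -> tuple[float, float]:
        return taylor_coefficients(self.base, self.T_night)


def day_night_parameter(
    dn: DayNightParam,
    protocol,
    t: float,
    eps: float = 0.0,
    eta: float = 0.0,
) -> float:
    """Effective rate at time ``t`` under day/night temperature forcing.

    Daytime (per the protocol's dawn/dusk test) evaluates the Arrhenius law
    at ``T_day + eps``, nighttime at ``T_night + eta``.  The fluctuations are
    applied to the exact law, not its Taylor linearization.
    """
    if protocol.is_day(t):
        return arrhenius_value(dn.base, dn.T_day + eps)
    return arrhenius_value(dn.base, dn.T_night + eta)
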