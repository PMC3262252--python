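"""Balance sums and the solvers that buffer environmental inputs.

If a subset S of parameters depends on an environmental quantity p (light
intensity, temperature), the first-order response of the periodic solution is

    dg/dp = sum_i sigma_i B_i U_i,    B_i = sum_{j in S} W_ij dk_j/dp.

The ``B_i`` are the *balance sums* and setting the leading ones to zero (the
*balance equations*) makes the orbit insensitive to p at first order.  Since
the sigma_i typically decay fast, zeroing only the first few sums already
shrinks ``||dg/dp||`` substantially.

Two concrete solvers are provided:

* light weights: the drive of light parameter k_j is ``k_j (c_j alpha + d_j)
  theta(t)`` with ``c_j + d_j = 1``, so ``dk_j/d alpha = k_j c_j`` and in
  relative (log-parameter) mode the balance sums are ``sum_j W~_ij c_j``.
  A chosen split of fixed/free weights turns the first r balance equations
  into an r x r linear system for the free c_j.

* activation energies: with Arrhenius dependence, ``dk_j/dT = k_j E_j/RT^2``
  so the balance sums are proportional to ``sum_j W_ij k_j E_j``.  Since
  ``k_j E_j > 0``, the i-th equation is solvable only if the W_ij of the
  subset do not all share one sign.  Energies are bounded to [1, 150] kJ/mol,
  so the solver minimises the sigma-weighted sums by bound-constrained least
  squares rather than zeroing them exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .arrhenius import ENERGY_BOUNDS, GAS_CONSTANT, ArrheniusParam
from .model import LightModification
from .sensitivity import PCDecomposition

__all__ = [
    "BalanceSpec",
    "BalanceReport",
    "EnergyAssignment",
    "BalanceInfeasibleError",
    "balance_sums",
    "solvability_check",
    "solve_light_balance",
    "arrhenius_balance_sums",
    "solve_energy_balance",
]


class BalanceInfeasibleError(RuntimeError):
    """Raised when the sign condition rules out every targeted equation."""


@dataclass(frozen=True)
class BalanceSpec:
    """A parameter subset S and the derivatives dk_j/dp over it."""

    subset: list[str]
    dkdp: np.ndarray
    n_eqs: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "dkdp", np.asarray(self.dkdp, dtype=float))
        if len(self.subset) == 0:
            raise ValueError("balance subset must be non-empty")
        if len(self.dkdp) != len(self.subset):
            raise ValueError("dkdp must have one entry per subset parameter")


@dataclass
class BalanceReport:
    """Balance sums B_i with their sigma weights, as a tidy table."""

    sums: np.ndarray          # B_i, i = 1..s
    sigma: np.ndarray
    response_norm: float      # (sum_i sigma_i^2 B_i^2)^(1/2)
    label: str = ""
    sums_before: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "i": np.arange(1, len(self.sums) + 1),
                "sigma_i": self.sigma,
                "balance_sum": self.sums,
                "sigma_weighted_sum": self.sigma * self.sums,
            }
        )
        if self.sums_before is not None:
            df["balance_sum_before"] = self.sums_before
        return df


def _subset_indices(pc: PCDecomposition, subset: list[str]) -> np.ndarray:
    try:
        return np.array([pc.param_names.index(n) for n in subset], dtype=int)
    except ValueError as err:
        raise KeyError(f"subset parameter not in decomposition: {err}")


def balance_sums(pc: PCDecomposition, spec: BalanceSpec, label: str = "") -> BalanceReport:
    """Evaluate B_i = sum_{j in S} W_ij dk_j/dp for every component i.

    The W of the decomposition's mode is used, so in relative mode ``dkdp``
    should hold relative derivatives d(log k_j)/dp.
    """
    idx = _subset_indices(pc, spec.subset)
    B = pc.W[:, idx] @ spec.dkdp
    norm = float(np.sqrt(np.sum((pc.sigma * B) ** 2)))
    return BalanceReport(sums=B, sigma=pc.sigma.copy(), response_norm=norm, label=label)


def solvability_check(
    pc_or_W: PCDecomposition | np.ndarray,
    subset: list[str] | np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-equation feasibility flags from the sign condition.

    Equation i is solvable with positive unknowns (such as ``k_j E_j``) only
    if the entries ``W_ij * weights_j`` over the subset do not all share one
    sign.  Returns a boolean array (True = feasible).  Accepts either a
    decomposition plus parameter names, or a raw W matrix plus column
    indices.
    """
    if isinstance(pc_or_W, PCDecomposition):
        idx = _subset_indices(pc_or_W, list(subset))
        W = pc_or_W.W
    else:
        W = np.asarray(pc_or_W)
        idx = np.asarray(subset, dtype=int)
    rows = W[:, idx]
    if weights is not None:
        rows = rows * np.asarray(weights)[None, :]
    pos = rows > 0
    neg = rows < 0
    return pos.any(axis=1) & neg.any(axis=1)


def solve_light_balance(
    pc: PCDecomposition,
    light_params: list[str],
    fixed_c: dict[str, float] | None = None,
    r: int | None = None,
    cond_max: float = 1e10,
) -> LightModification:
    """Solve the first r balance equations for the free light weights c_j.

    The decomposition must be in relative mode (the light-weight balance
    sums are ``sum_j W~_ij c_j``).  Entries listed in ``fixed_c`` are held at
    the given values and moved to the right-hand side; the number of free
    weights must equal ``r`` (default: all weights not fixed).  Raises on an
    ill-conditioned system, which usually means a different fixed/free split
    is needed.
    """
    if pc.mode != "relative":
        raise ValueError("light balance uses relative (log-parameter) mode")
    fixed_c = dict(fixed_c or {})
    unknown = set(fixed_c) - set(light_params)
    if unknown:
        raise KeyError(f"fixed weights for non-light parameters: {sorted(unknown)}")
    free = [p for p in light_params if p not in fixed_c]
    if r is None:
        r = len(free)
    if len(free) != r:
        raise ValueError(f"{len(free)} free weights but r = {r} balance equations")
    if r > pc.n_components:
        raise ValueError(f"r = {r} exceeds the {pc.n_components} available components")
    idx_free = _subset_indices(pc, free)
    A = pc.W[:r, idx_free]
    b = np.zeros(r)
    if fixed_c:
        idx_fix = _subset_indices(pc, list(fixed_c))
        b = -pc.W[:r, idx_fix] @ np.array([fixed_c[p] for p in fixed_c])
    if r > 0:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > cond_max:
            raise np.linalg.LinAlgError(
                f"balance system is ill-conditioned (cond = {cond:.2e}); "
                "try a different fixed/free split of the light weights"
            )
        c_free = np.linalg.solve(A, b)
    else:
        c_free = np.array([])
    c = dict(fixed_c)
    c.update({p: float(v) for p, v in zip(free, c_free)})
    return LightModification(c={p: float(c[p]) for p in light_params})


def arrhenius_balance_sums(
    pc: PCDecomposition,
    temp_params: list[str],
    k: np.ndarray | dict[str, float],
    E: np.ndarray | dict[str, float],
    T: float,
    label: str = "",
) -> BalanceReport:
    """Balance sums ``B_i = sum_j W_ij k_j E_j`` for temperature input.

    ``report.sums`` holds the convenient table form ``sum_j W_ij k_j E_j``;
    the physical sums (per kelvin) carry the extra ``1/(R T^2)`` factor from
    ``dk_j/dT = k_j E_j / (R T^2)`` and are exposed via
    :func:`true_temperature_sums`.  For a day/night model call this twice,
    once with the day values ``k_j(T_D)`` and once with ``k_j(T_N)``.
    """
    kv = _aligned(k, temp_params, "k")
    Ev = _aligned(E, temp_params, "E")
    spec = BalanceSpec(subset=list(temp_params), dkdp=kv * Ev, n_eqs=pc.n_components)
    report = balance_sums(pc, spec, label=label or f"T={T}")
    report.temperature = T  # type: ignore[attr-defined]
    return report


def true_temperature_sums(report: BalanceReport, T: float) -> np.ndarray:
    """Convert table-form sums (W k E) to physical sums per kelvin."""
    return report.sums / (GAS_CONSTANT * T * T)


def _aligned(v, names: list[str], what: str) -> np.ndarray:
    if isinstance(v, dict):
        missing = set(names) - set(v)
        if missing:
            raise KeyError(f"missing {what} values for {sorted(missing)}")
        return np.array([float(v[n]) for n in names])
    v = np.asarray(v, dtype=float)
    if len(v) != len(names):
        raise ValueError(f"{what} must have one value per temperature parameter")
    return v


@dataclass
class EnergyAssignment:
    """Solved activation energies over the temperature-sensitive subset."""

    params: list[str]
    E: np.ndarray
    fixed: dict[str, float]
    report: BalanceReport
    converged: bool = True
    n_iterations: int = 1

    def as_dict(self) -> dict[str, float]:
        return {p: float(e) for p, e in zip(self.params, self.E)}

    def arrhenius_params(
        self, k_ref: dict[str, float], T_ref: float, **kwargs
    ) -> dict[str, ArrheniusParam]:
        return {
            p: ArrheniusParam(energy=float(e), k_ref=float(k_ref[p]), T_ref=T_ref, **kwargs)
            for p, e in zip(self.params, self.E)
        }


def solve_energy_balance(
    pc: PCDecomposition,
    temp_params: list[str],
    k: np.ndarray | dict[str, float],
    fixed_E: dict[str, float] | None = None,
    r: int = 2,
    bounds: tuple[float, float] = ENERGY_BOUNDS,
    T: float = 288.15,
    refresh: "object" = None,
    iter_tol: float = 1e-3,
    max_iterations: int = 20,
    target_mean: float | None = None,
) -> EnergyAssignment:
    """Choose activation energies minimising the leading balance sums.

    Minimises ``sum_{i<=r} (sigma_i B_i)^2`` with ``B_i = sum_j W_ij k_j E_j``
    over the free energies, subject to the bounds (kJ/mol), by constrained
    linear least squares.  Raises :class:`BalanceInfeasibleError` when the
    sign condition fails for every targeted equation (all ``W_ij k_j`` of one
    sign for each i <= r), since ``k_j E_j > 0`` then forces ``B_i != 0``.

    ``refresh``, if given, is a callable ``refresh(E: dict) ->
    PCDecomposition`` used for the iterative mode: after each solve the
    decomposition is recomputed at the parameterization implied by the new
    energies and the system re-solved, until the energies move by less than
    ``iter_tol`` kJ/mol or ``max_iterations`` is reached.
    """
    fixed_E = dict(fixed_E or {})
    unknown = set(fixed_E) - set(temp_params)
    if unknown:
        raise KeyError(f"fixed energies for unknown parameters: {sorted(unknown)}")
    free = [p for p in temp_params if p not in fixed_E]
    if len(free) < r:
        raise ValueError(f"need at least r = {r} free energies, have {len(free)}")

    def solve_once(pc_cur: PCDecomposition, k_cur) -> np.ndarray:
        kv = _aligned(k_cur, temp_params, "k")
        kmap = dict(zip(temp_params, kv))
        feasible = solvability_check(pc_cur, temp_params, weights=kv)[:r]
        if not feasible.any():
            raise BalanceInfeasibleError(
                f"every targeted balance equation (i <= {r}) has W_ij k_j of a "
                "single sign over the subset; with k_j E_j > 0 the sums cannot "
                "be balanced — the sign condition fails"
            )
        idx_free = _subset_indices(pc_cur, free)
        A = pc_cur.sigma[:r, None] * pc_cur.W[:r, idx_free] * np.array(
            [kmap[p] for p in free]
        )[None, :]
        b = np.zeros(r)
        if fixed_E:
            idx_fix = _subset_indices(pc_cur, list(fixed_E))
            contrib = pc_cur.sigma[:r, None] * pc_cur.W[:r, idx_fix] * np.array(
                [kmap[p] * fixed_E[p] for p in fixed_E]
            )[None, :]
            b = -contrib.sum(axis=1)
        res = lsq_linear(A, b, bounds=bounds, method="bvls")
        return np.asarray(res.x)

    pc_cur, k_cur = pc, k
    E_free = solve_once(pc_cur, k_cur)
    n_iter, converged = 1, True
    if refresh is not None:
        converged = False
        for n_iter in range(2, max_iterations + 1):
            E_map = _assemble(temp_params, free, E_free, fixed_E)
            out = refresh(E_map)
            pc_cur, k_cur = out if isinstance(out, tuple) else (out, k)
            E_new = solve_once(pc_cur, k_cur)
            shift = float(np.max(np.abs(E_new - E_free)))
            E_free = E_new
            if shift < iter_tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"energy rebalancing not converged after {max_iterations} "
                "iterations; returning the last iterate"
            )
    if target_mean is not None and not fixed_E:
        # the sums are linear in E, so rescaling an exact solution keeps it
        # exact; lift the energies toward a physiological mean within bounds
        scale = target_mean / max(float(np.mean(E_free)), 1e-12)
        scale = min(scale, bounds[1] / float(np.max(E_free)))
        if scale * float(np.min(E_free)) >= bounds[0]:
            E_free = E_free * scale
    E_map = _assemble(temp_params, free, E_free, fixed_E)
    E_vec = np.array([E_map[p] for p in temp_params])
    report = arrhenius_balance_sums(pc_cur, temp_params, k_cur, E_vec, T, label="solved")
    return EnergyAssignment(
        params=list(temp_params),
        E=E_vec,
        fixed=fixed_E,
        report=report,
        converged=converged,
        n_iterations=n_iter,
    )


def _assemble(
    temp_params: list[str], free: list[str], E_free: np.ndarray, fixed_E: dict[str, float]
) -> dict[str, float]:
    out = dict(fixed_E)
    out.update({p: float(e) for p, e in zip(free, E_free)})
    return {p: out[p] for p in temp_params}
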