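"""Principal-component global sensitivity analysis of the entrained orbit.

The object of study is the linear response operator M mapping a parameter
perturbation ``dk`` to the first-order change of the periodic solution,
``dg(t) = sum_j dg/dk_j(t) dk_j``, viewed in the Hilbert space of periodic
time series with inner product

    <u, v> = sum_m integral_0^tau u_m(t) v_m(t) dt

(unit state weights by default, trapezoidal quadrature on the orbit grid).
The Gram matrix ``G_ij = <dg/dk_i, dg/dk_j>`` of M*M has eigenvalues
``sigma_i^2``; the orthonormal eigenvectors are the principal parameter
directions ``V_i``, and ``U_i(t) = M V_i / sigma_i`` are the orthonormal
principal time series, so that

    dg = sum_i sigma_i (sum_j W_ij dk_j) U_i,    W = V^-1 = V^T.

In relative (log-parameter) mode the same sigma and U are kept and the
weight matrix becomes ``W~_ij = k_j W_ij`` (and ``V~ = diag(k) V``), which is
the convenient convention for balance equations; note this is a rescaling of
the absolute decomposition, not a fresh SVD of M diag(k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .model import light_value
from .orbit import (
    OrbitConvergenceError,
    PeriodicOrbit,
    find_entrained_orbit,
    peak_phases,
)

__all__ = [
    "SensitivityMatrix",
    "PCDecomposition",
    "PhaseSensitivity",
    "compute_sensitivities",
    "gram_matrix",
    "principal_components",
    "predicted_response",
    "phase_sensitivity",
    "power_spectrum",
    "hilbert_norm",
    "trapezoid_weights",
]


def trapezoid_weights(ts: np.ndarray) -> np.ndarray:
    w = np.empty_like(ts)
    w[1:-1] = 0.5 * (ts[2:] - ts[:-2])
    w[0] = 0.5 * (ts[1] - ts[0])
    w[-1] = 0.5 * (ts[-1] - ts[-2])
    return w


def hilbert_norm(u: np.ndarray, ts: np.ndarray, state_weights: np.ndarray | None = None) -> float:
    """Norm of a periodic time-series perturbation, shape (n_states, n_times)."""
    w = trapezoid_weights(ts)
    sw = np.ones(u.shape[0]) if state_weights is None else np.asarray(state_weights)
    return float(np.sqrt(np.einsum("m,mt,mt,t->", sw, u, u, w)))


@dataclass
class SensitivityMatrix:
    """Samples of S_mj(t) = dg_m/dk_j on the orbit grid."""

    orbit: PeriodicOrbit
    ts: np.ndarray
    S: np.ndarray  # (n_states, n_params, n_times)
    method: str
    _spline: CubicSpline | None = field(default=None, repr=False)

    @property
    def param_names(self) -> list[str]:
        return self.orbit.model.param_names

    @property
    def spline(self) -> CubicSpline:
        if self._spline is None:
            s = self.S.copy()
            s[..., -1] = s[..., 0]
            self._spline = CubicSpline(self.ts, s, axis=2, bc_type="periodic")
        return self._spline

    def at(self, t: float) -> np.ndarray:
        return self.spline(t % self.orbit.period)

    def time_derivative_at(self, t: float) -> np.ndarray:
        """dS/dt from the variational right-hand side along the orbit."""
        seg = self.orbit.segment_at(t)
        th = (
            seg.theta
            if self.orbit.protocol.mode == "square"
            else light_value(self.orbit.protocol, t)
        )
        x = self.orbit(t)
        cm = self.orbit.model.compiled
        J = cm.jac_x(x, seg.k_eff, th)
        Fk = cm.jac_k(x, seg.k_eff, th)
        return J @ self.at(t) + Fk


def compute_sensitivities(
    orbit: PeriodicOrbit,
    method: str = "variational",
    tol: float = 1e-9,
    max_cycles: int = 200,
    rel_step: float = 1e-4,
) -> SensitivityMatrix:
    """Compute dg/dk_j along the entrained orbit.

    ``"variational"`` integrates the forward sensitivity equations
    ``dZ_j/dt = J_x(t) Z_j + df/dk_j`` together with the state over repeated
    forcing cycles until Z is periodic; because the orbit is asymptotically
    stable this fixed-point iteration converges geometrically.

    ``"finite_difference"`` re-converges the orbit at ``k_j (1 +/- h)`` and
    takes central differences (h = ``rel_step``).

    A parameter perturbs its day and night effective values together, so the
    result is the sensitivity to a sustained parameter change.
    """
    if method == "variational":
        return _variational(orbit, tol, max_cycles)
    if method == "finite_difference":
        return _finite_difference(orbit, rel_step)
    raise ValueError(f"unknown sensitivity method {method!r}")


def _variational(orbit: PeriodicOrbit, tol: float, max_cycles: int) -> SensitivityMatrix:
    model = orbit.model
    cm = model.compiled
    n, s = model.n_states, model.n_params
    smoothed = orbit.protocol.mode == "smoothed"
    protocol = orbit.protocol

    def make_rhs(seg):
        def f(t, y):
            x, Z = y[:n], y[n:].reshape(n, s)
            th = seg.theta if not smoothed else light_value(protocol, t)
            dx = cm.rhs(x, seg.k_eff, th)
            dZ = cm.jac_x(x, seg.k_eff, th) @ Z + cm.jac_k(x, seg.k_eff, th)
            return np.concatenate([dx, dZ.ravel()])

        return f

    y = np.concatenate([orbit.x0, np.zeros(n * s)])
    for cycle in range(1, max_cycles + 1):
        z_prev = y[n:].copy()
        for seg in orbit.segments:
            sol = solve_ivp(
                make_rhs(seg),
                (seg.t0, seg.t1),
                y,
                method="LSODA",
                rtol=orbit.rtol,
                atol=orbit.atol,
            )
            if not sol.success:
                raise OrbitConvergenceError(
                    "variational integration failed; the orbit may not be "
                    "asymptotically stable — try method='finite_difference'",
                    [],
                )
            y = sol.y[:, -1]
        y[:n] = orbit.x0  # keep the base trajectory pinned to the orbit
        res = float(np.max(np.abs(y[n:] - z_prev)))
        if res < tol:
            break
    else:
        raise OrbitConvergenceError(
            f"sensitivity equations not periodic after {max_cycles} cycles "
            f"(residual {res:.3e}); try method='finite_difference'",
            [res],
        )

    # sampling cycle
    ts = orbit.ts
    S = np.empty((n, s, len(ts)))
    ysamp = y.copy()
    sols = []
    for seg in orbit.segments:
        sol = solve_ivp(
            make_rhs(seg),
            (seg.t0, seg.t1),
            ysamp,
            method="LSODA",
            rtol=orbit.rtol,
            atol=orbit.atol,
            dense_output=True,
        )
        sols.append(sol)
        ysamp = sol.y[:, -1]
    for i, t in enumerate(ts):
        for sol in sols:
            if sol.t[0] - 1e-12 <= t <= sol.t[-1] + 1e-12:
                S[:, :, i] = sol.sol(np.clip(t, sol.t[0], sol.t[-1]))[n:].reshape(n, s)
                break
    return SensitivityMatrix(orbit=orbit, ts=ts, S=S, method="variational")


def _finite_difference(orbit: PeriodicOrbit, rel_step: float) -> SensitivityMatrix:
    model = orbit.model
    n, s = model.n_states, model.n_params
    ts = orbit.ts
    S = np.empty((n, s, len(ts)))
    for j in range(s):
        delta = rel_step * orbit.k[j]
        samples = []
        for sign in (+1.0, -1.0):
            kpert = orbit.k.copy()
            kpert[j] += sign * delta
            pert = find_entrained_orbit(
                model,
                orbit.protocol,
                k=kpert,
                alpha=orbit.alpha,
                temp=orbit.temp,
                x0=orbit.x0,
                tol=min(1e-10, rel_step * 1e-4),
                n_grid=len(ts) - 1,
                rtol=orbit.rtol,
                atol=orbit.atol,
            )
            samples.append(pert.values)
        S[:, j, :] = (samples[0] - samples[1]) / (2.0 * delta)
    return SensitivityMatrix(orbit=orbit, ts=ts, S=S, method="finite_difference")


# -- decomposition ---------------------------------------------------------

def gram_matrix(sens: SensitivityMatrix, state_weights: np.ndarray | None = None) -> np.ndarray:
    """G_ij = <dg/dk_i, dg/dk_j> by trapezoidal quadrature on the grid."""
    w = trapezoid_weights(sens.ts)
    sw = np.ones(sens.S.shape[0]) if state_weights is None else np.asarray(state_weights)
    G = np.einsum("m,mit,mjt,t->ij", sw, sens.S, sens.S, w)
    return 0.5 * (G + G.T)


@dataclass
class PCDecomposition:
    """SVD structure of the sensitivity operator on the orbit grid.

    ``sigma`` descending; columns of ``V`` are the principal parameter
    directions; ``W`` satisfies ``dg = sum_i sigma_i (W dk)_i U_i`` for the
    mode's notion of ``dk`` (absolute changes, or relative changes
    ``dk_j/k_j`` in relative mode, where ``W`` holds ``W~_ij = k_j W_ij``).
    ``U`` has shape (n_pc, n_states, n_times).
    """

    sigma: np.ndarray
    V: np.ndarray
    W: np.ndarray
    U: np.ndarray
    G: np.ndarray
    ts: np.ndarray
    k: np.ndarray
    mode: str
    param_names: list[str]
    state_names: list[str]
    state_weights: np.ndarray | None = None
    degenerate: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return len(self.sigma)

    @property
    def W_absolute(self) -> np.ndarray:
        """W against absolute parameter changes, regardless of mode."""
        return self.W / self.k[None, :] if self.mode == "relative" else self.W


def principal_components(
    sens: SensitivityMatrix,
    mode: str = "absolute",
    G: np.ndarray | None = None,
    state_weights: np.ndarray | None = None,
    degeneracy_rtol: float = 1e-8,
) -> PCDecomposition:
    """Eigendecomposition of the Gram matrix into (sigma_i, V_i, W, U_i).

    ``mode="relative"`` applies the log-parameter convention: sigma and the
    principal time series are those of the absolute decomposition while the
    weight matrix is rescaled to ``W~_ij = k_j W_ij`` (and ``V~ = diag(k) V``).
    """
    if mode not in ("absolute", "relative"):
        raise ValueError(f"unknown mode {mode!r}")
    if G is None:
        G = gram_matrix(sens, state_weights)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(-evals, kind="stable")
    evals = np.clip(evals[order], 0.0, None)
    V = evecs[:, order]
    sigma = np.sqrt(evals)
    W = V.T  # V is orthogonal
    floor = max(sigma[0], 1e-300) * 1e-12
    n, _, nt = sens.S.shape
    U = np.zeros((len(sigma), n, nt))
    for i in range(len(sigma)):
        if sigma[i] > floor:
            U[i] = np.einsum("mjt,j->mt", sens.S, V[:, i]) / sigma[i]
    degenerate = np.zeros(len(sigma), dtype=bool)
    for i in range(len(sigma) - 1):
        if sigma[i] > 0 and (sigma[i] - sigma[i + 1]) < degeneracy_rtol * sigma[i]:
            degenerate[i] = degenerate[i + 1] = True
    k = np.asarray(sens.orbit.k, dtype=float)
    if mode == "relative":
        W = W * k[None, :]
        V = V * k[:, None]
    return PCDecomposition(
        sigma=sigma,
        V=V,
        W=W,
        U=U,
        G=G,
        ts=sens.ts,
        k=k,
        mode=mode,
        param_names=list(sens.param_names),
        state_names=list(sens.orbit.model.state_names),
        state_weights=state_weights,
        degenerate=degenerate,
    )


def predicted_response(pc: PCDecomposition, dk: np.ndarray) -> np.ndarray:
    """First-order prediction of dg(t) for an absolute parameter change dk.

    Returns an array of shape (n_states, n_times) on the decomposition grid:
    ``dg = sum_i sigma_i (sum_j W_ij dk_j) U_i``.
    """
    dk = np.asarray(dk, dtype=float)
    amp = pc.sigma * (pc.W_absolute @ dk)
    return np.einsum("i,imt->mt", amp, pc.U)


# -- phase sensitivities ---------------------------------------------------

@dataclass
class PhaseSensitivity:
    """dphi_m/dk_j in hours per parameter unit (NaN rows where undefined).

    ``pinned[m]`` marks components whose maximum sits at a light-switch
    corner (the one-sided slopes bracket zero there); such a peak does not
    move under small parameter changes, so its row is exactly zero.
    """

    dphi: np.ndarray  # (n_states, n_params)
    phases: list[float | None]
    state_names: list[str]
    param_names: list[str]
    mode: str = "absolute"
    pinned: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dphi, index=self.state_names, columns=self.param_names)


def phase_sensitivity(
    orbit: PeriodicOrbit,
    sens: SensitivityMatrix,
    pc: PCDecomposition | None = None,
    route: str = "direct",
    mode: str = "absolute",
    curvature_tol: float = 1e-10,
) -> PhaseSensitivity:
    """Sensitivity of each component's peak time to each parameter.

    At the peak, ``dg_m/dt(phi_m) = 0``; differentiating this condition
    gives the implicit-function formula

        dphi_m/dk_j = - (dS_mj/dt)(phi_m) / (d^2 g_m/dt^2)(phi_m).

    ``route="pc"`` evaluates the same quantity through the principal-
    component expansion ``- sum_i sigma_i W_ij dU_im/dt(phi_m) / g_m''`` and
    must agree with the direct route to algebraic precision.  ``mode=
    "relative"`` returns hours per unit relative parameter change (columns
    scaled by k_j).
    """
    model = orbit.model
    phases_all = peak_phases(orbit)
    n, s = model.n_states, model.n_params
    dphi = np.full((n, s), np.nan)
    pinned = np.zeros(n, dtype=bool)
    phases: list[float | None] = []
    dt = orbit.ts[1] - orbit.ts[0]
    for m, comp in enumerate(phases_all.components):
        phi = comp.peak_time
        phases.append(phi)
        if phi is None:
            continue
        edge = _pinned_at_edge(orbit, m, phi, 2.0 * dt)
        if edge is not None:
            # corner maximum at a light switch: the peak time is locked to
            # the switch for small parameter changes, so the derivative is 0
            dphi[m, :] = 0.0
            pinned[m] = True
            phases[-1] = edge
            continue
        seg = orbit.segment_at(phi)
        th = seg.theta if orbit.protocol.mode == "square" else light_value(orbit.protocol, phi)
        x = orbit(phi)
        cm = model.compiled
        f = cm.rhs(x, seg.k_eff, th)
        gdd = (cm.jac_x(x, seg.k_eff, th) @ f)[m]
        if not np.isfinite(gdd) or abs(gdd) < curvature_tol or gdd > 0:
            continue  # flat or non-maximal curvature: phase shift undefined
        Sdot = sens.time_derivative_at(phi)  # (n, s)
        if route == "direct":
            dphi[m, :] = -Sdot[m, :] / gdd
        elif route == "pc":
            if pc is None:
                raise ValueError("route='pc' requires a PCDecomposition")
            Vabs = pc.V / pc.k[:, None] if pc.mode == "relative" else pc.V
            Wabs = pc.W_absolute
            floor = max(pc.sigma[0], 1e-300) * 1e-12
            Udot_m = np.zeros(len(pc.sigma))
            for i in range(len(pc.sigma)):
                if pc.sigma[i] > floor:
                    Udot_m[i] = (Sdot[m, :] @ Vabs[:, i]) / pc.sigma[i]
            dphi[m, :] = -(pc.sigma * Udot_m) @ Wabs / gdd
        else:
            raise ValueError(f"unknown route {route!r}")
    if mode == "relative":
        dphi = dphi * np.asarray(orbit.k)[None, :]
    elif mode != "absolute":
        raise ValueError(f"unknown mode {mode!r}")
    return PhaseSensitivity(
        dphi=dphi,
        phases=phases,
        state_names=list(model.state_names),
        param_names=list(model.param_names),
        mode=mode,
        pinned=pinned,
    )


def _pinned_at_edge(orbit: PeriodicOrbit, m: int, phi: float, tol: float) -> float | None:
    """Return the switch time if component m's peak is a corner maximum.

    A square-wave light switch at time ``t_b`` pins the maximum when the
    one-sided slopes bracket zero (dg_m/dt > 0 just before, < 0 just after).
    Only meaningful for square light protocols.
    """
    if orbit.protocol.mode != "square":
        return None
    tau = orbit.period
    for t_b in (orbit.protocol.dawn, orbit.protocol.dusk):
        d = (phi - t_b + tau / 2.0) % tau - tau / 2.0
        if abs(d) <= tol:
            before = orbit.derivative(t_b - 1e-9)[m]
            after = orbit.derivative(t_b + 1e-9)[m]
            if before > 0 > after:
                return t_b % tau
    return None


# -- power sensitivity spectrum -------------------------------------------

def power_spectrum(
    pc: PCDecomposition,
    top_i: int = 4,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-parameter ranking by ``max_i |sigma_i W_ij|`` over the leading PCs.

    Returns a DataFrame sorted descending, with one ``sigma_w_i`` column per
    principal component i = 1..top_i, the max, and its log10.  With
    ``threshold`` given, only parameters whose max exceeds ``threshold``
    times the global maximum are kept (e.g. 0.3 for the 30%-of-maximum
    filter used to pick temperature-sensitive parameters).
    """
    top_i = min(top_i, len(pc.sigma))
    mat = np.abs(pc.sigma[:top_i, None] * pc.W[:top_i, :])  # (top_i, s)
    best = mat.max(axis=0)
    data = {"parameter": pc.param_names}
    for i in range(top_i):
        data[f"sigma_w_{i + 1}"] = mat[i]
    df = pd.DataFrame(data)
    df["max_sigma_w"] = best
    with np.errstate(divide="ignore"):
        df["log10_max"] = np.log10(best)
    df = df.sort_values("max_sigma_w", ascending=False, kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    if threshold is not None:
        df = df[df["max_sigma_w"] >= threshold * df["max_sigma_w"].max()].reset_index(drop=True)
    return df
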