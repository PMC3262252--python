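"""Convergence to the entrained periodic orbit and phase extraction.

A forced clock model with a stable entrained solution is converged by
iterating the period map: the state is integrated cycle by cycle until the
sup-norm residual ``||x(n*tau) - x((n-1)*tau)||`` falls below tolerance.
Within a cycle the square light signal is piecewise constant, so each cycle
is integrated in day/night segments with an autonomous right-hand side,
which keeps the stiff integrator accurate across the dawn/dusk switches.

Temperature enters through per-segment parameter values: during the lit
interval temperature-sensitive parameters take their value at the day
temperature, at night their value at the night temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .arrhenius import ArrheniusParam, arrhenius_value
from .model import ClockModel, LightProtocol, light_value

__all__ = [
    "PeriodicOrbit",
    "PhaseSet",
    "ComponentPhases",
    "FreeRunResult",
    "TemperatureSchedule",
    "OrbitConvergenceError",
    "find_entrained_orbit",
    "peak_phases",
    "free_running_period",
]

RTOL_DEFAULT = 1e-9
ATOL_DEFAULT = 1e-12
N_GRID_DEFAULT = 2400  # samples per 24 h cycle (0.01 h)


class OrbitConvergenceError(RuntimeError):
    """Raised when the period-map iteration fails to converge."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class TemperatureSchedule:
    """Day/night temperatures and the Arrhenius description per parameter."""

    params: dict[str, ArrheniusParam]
    T_day: float
    T_night: float

    def day_values(self, eps: float = 0.0) -> dict[str, float]:
        return {n: arrhenius_value(p, self.T_day + eps) for n, p in self.params.items()}

    def night_values(self, eta: float = 0.0) -> dict[str, float]:
        return {n: arrhenius_value(p, self.T_night + eta) for n, p in self.params.items()}


@dataclass
class Segment:
    """One piece of a forcing cycle with constant theta and parameters."""

    t0: float
    t1: float
    theta: float
    is_day: bool
    k_eff: np.ndarray


def cycle_segments(
    model: ClockModel,
    protocol: LightProtocol,
    k: np.ndarray | None = None,
    alpha: float = 1.0,
    temp: TemperatureSchedule | None = None,
    eps: float = 0.0,
    eta: float = 0.0,
    t_offset: float = 0.0,
) -> list[Segment]:
    """Split one forcing cycle starting at ``t_offset`` into segments.

    ``t_offset`` is a phase within the cycle (0 starts at midnight-side,
    ``protocol.dawn`` starts at dawn).  Light regulation weights and the
    day's light intensity ``alpha`` scale the light parameters; temperature
    sets the temperature-sensitive parameters per segment.
    """
    tau = protocol.period
    edges = sorted({0.0, protocol.dawn, protocol.dusk, tau})
    base = np.array(model.param_values if k is None else k, dtype=float)

    def seg_params(is_day: bool) -> np.ndarray:
        keff = base.copy()
        if temp is not None:
            vals = temp.day_values(eps) if is_day else temp.night_values(eta)
            for name, v in vals.items():
                keff[model.param_index(name)] = v
        if len(model.light_params):
            keff[model.light_idx] = keff[model.light_idx] * model.light_scale(alpha)
        return keff

    pieces = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        mid = 0.5 * (a + b)
        is_day = protocol.dawn <= mid < protocol.dusk
        pieces.append((a, b, is_day))
    # rotate so the cycle starts at t_offset
    off = t_offset % tau
    if off > 0:
        rotated = []
        for a, b, d in pieces + [(a + tau, b + tau, d) for a, b, d in pieces]:
            lo, hi = max(a, off), min(b, off + tau)
            if hi - lo > 1e-12:
                rotated.append((lo, hi, d))
        pieces = rotated
    k_day, k_night = seg_params(True), seg_params(False)
    return [
        Segment(a, b, 1.0 if d else 0.0, d, k_day if d else k_night) for a, b, d in pieces
    ]


def _integrate_segments(
    model: ClockModel,
    protocol: LightProtocol,
    segments: list[Segment],
    x0: np.ndarray,
    t_base: float = 0.0,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    dense: bool = False,
):
    """Integrate across the given segments; return final state (+ solutions)."""
    cm = model.compiled
    smoothed = protocol.mode == "smoothed"
    x = np.asarray(x0, dtype=float)
    sols = []
    for seg in segments:
        if smoothed:
            def f(t, y, _k=seg.k_eff):
                return cm.rhs(y, _k, light_value(protocol, t))
        else:
            def f(t, y, _k=seg.k_eff, _th=seg.theta):
                return cm.rhs(y, _k, _th)
        sol = solve_ivp(
            f,
            (t_base + seg.t0, t_base + seg.t1),
            x,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=dense,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise OrbitConvergenceError(
                f"integration failed on [{seg.t0}, {seg.t1}]: {sol.message}", []
            )
        x = sol.y[:, -1]
        if dense:
            sols.append(sol)
    return (x, sols) if dense else x


@dataclass
class PeriodicOrbit:
    """The entrained solution g(t) sampled over one forcing cycle.

    ``ts`` holds ``n_grid + 1`` uniform times on [0, tau] (both endpoints,
    equal up to the periodicity residual); ``values`` is states x times.
    """

    model: ClockModel
    protocol: LightProtocol
    k: np.ndarray
    alpha: float
    ts: np.ndarray
    values: np.ndarray
    x0: np.ndarray
    residual: float
    n_cycles: int
    segments: list[Segment]
    temp: TemperatureSchedule | None = None
    rtol: float = RTOL_DEFAULT
    atol: float = ATOL_DEFAULT
    _spline: CubicSpline | None = field(default=None, repr=False)

    @property
    def period(self) -> float:
        return self.protocol.period

    @property
    def spline(self) -> CubicSpline:
        if self._spline is None:
            y = self.values.copy()
            y[:, -1] = y[:, 0]  # close up the periodicity residual
            self._spline = CubicSpline(self.ts, y, axis=1, bc_type="periodic")
        return self._spline

    def __call__(self, t):
        return self.spline(np.asarray(t) % self.period)

    def segment_at(self, t: float) -> Segment:
        tm = t % self.period
        for seg in self.segments:
            if seg.t0 <= tm < seg.t1 or (seg is self.segments[-1] and tm >= seg.t1):
                return seg
        return self.segments[-1]

    def derivative(self, t: float) -> np.ndarray:
        """dg/dt from the right-hand side evaluated on the orbit."""
        seg = self.segment_at(t)
        th = seg.theta if self.protocol.mode == "square" else light_value(self.protocol, t)
        return self.model.compiled.rhs(self(t), seg.k_eff, th)


def find_entrained_orbit(
    model: ClockModel,
    protocol: LightProtocol | None = None,
    k: np.ndarray | None = None,
    alpha: float = 1.0,
    temp: TemperatureSchedule | None = None,
    x0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_cycles: int = 200,
    min_cycles: int = 3,
    n_grid: int = N_GRID_DEFAULT,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
) -> PeriodicOrbit:
    """Converge the forced model to its attracting entrained orbit.

    Iterates full forcing cycles from ``x0`` until the period-map residual
    ``||x(n tau) - x((n-1) tau)||_inf`` drops below ``tol``, then samples one
    further cycle on a uniform grid of ``n_grid`` intervals.
    """
    protocol = protocol if protocol is not None else LightProtocol(period=model.forcing_period)
    kbase = np.array(model.param_values if k is None else k, dtype=float)
    segments = cycle_segments(model, protocol, kbase, alpha, temp)
    x = np.full(model.n_states, 0.1) if x0 is None else np.asarray(x0, dtype=float)

    residuals: list[float] = []
    for cycle in range(1, max_cycles + 1):
        x_new = _integrate_segments(model, protocol, segments, x, rtol=rtol, atol=atol)
        res = float(np.max(np.abs(x_new - x)))
        residuals.append(res)
        x = x_new
        if cycle >= min_cycles and res < tol:
            break
    else:
        raise OrbitConvergenceError(
            f"no entrained orbit after {max_cycles} cycles "
            f"(last residual {residuals[-1]:.3e})",
            residuals,
        )

    # sampling cycle
    x_start = x
    _, sols = _integrate_segments(
        model, protocol, segments, x_start, rtol=rtol, atol=atol, dense=True
    )
    tau = protocol.period
    ts = np.linspace(0.0, tau, n_grid + 1)
    values = np.empty((model.n_states, n_grid + 1))
    for i, t in enumerate(ts):
        values[:, i] = _eval_dense(sols, t)
    residual = float(np.max(np.abs(values[:, -1] - values[:, 0])))
    return PeriodicOrbit(
        model=model,
        protocol=protocol,
        k=kbase,
        alpha=alpha,
        ts=ts,
        values=values,
        x0=x_start,
        residual=residual,
        n_cycles=cycle,
        segments=segments,
        temp=temp,
        rtol=rtol,
        atol=atol,
    )


def _eval_dense(sols, t: float) -> np.ndarray:
    for sol in sols:
        if sol.t[0] - 1e-12 <= t <= sol.t[-1] + 1e-12:
            return sol.sol(np.clip(t, sol.t[0], sol.t[-1]))
    return sols[-1].sol(sols[-1].t[-1])


# -- peak phases ----------------------------------------------------------

@dataclass
class ComponentPhases:
    """Peak/trough times of one component within the forcing cycle."""

    state: str
    peaks: list[tuple[float, float]]  # (time, level)
    troughs: list[tuple[float, float]]
    flat: bool = False
    multi_peak: bool = False

    @property
    def peak_time(self) -> float | None:
        """Time of the global maximum (None for flat components)."""
        if self.flat or not self.peaks:
            return None
        return max(self.peaks, key=lambda p: p[1])[0]

    @property
    def trough_time(self) -> float | None:
        if self.flat or not self.troughs:
            return None
        return min(self.troughs, key=lambda p: p[1])[0]


@dataclass
class PhaseSet:
    components: list[ComponentPhases]

    def __getitem__(self, state: str) -> ComponentPhases:
        for c in self.components:
            if c.state == state:
                return c
        raise KeyError(state)

    @property
    def peak_times(self) -> dict[str, float | None]:
        return {c.state: c.peak_time for c in self.components}


def _refine_extremum(ts: np.ndarray, y: np.ndarray, i: int, tau: float) -> tuple[float, float]:
    """Quadratic refinement of a grid extremum through 3 points (cyclic)."""
    n = len(ts) - 1  # last sample duplicates the first
    im, ip = (i - 1) % n, (i + 1) % n
    dt = ts[1] - ts[0]
    ym, y0, yp = y[im], y[i], y[ip]
    denom = ym - 2.0 * y0 + yp
    delta = 0.0 if abs(denom) < 1e-300 else 0.5 * (ym - yp) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    t_star = (ts[i] + delta * dt) % tau
    y_star = y0 - 0.25 * (ym - yp) * delta
    return t_star, y_star


def peak_phases(orbit: PeriodicOrbit, flat_tol: float = 1e-8) -> PhaseSet:
    """Locate peak and trough times of each component on the orbit.

    Grid extrema are refined by a local quadratic fit.  All local maxima
    are reported; the global maximum defines the component's phase.
    Components that are constant to within ``flat_tol`` (relative to the
    mean level) are flagged as having undefined phase.
    """
    tau = orbit.period
    comps = []
    n = len(orbit.ts) - 1
    for m, name in enumerate(orbit.model.state_names):
        y = orbit.values[m]
        yc = y[:n]  # one value per grid point, cyclic
        amp = float(yc.max() - yc.min())
        mean = float(yc.mean())
        if amp <= flat_tol * max(1.0, abs(mean)):
            comps.append(ComponentPhases(name, [], [], flat=True))
            continue
        peaks, troughs = [], []
        dt = orbit.ts[1] - orbit.ts[0]
        for i in range(n):
            ym, y0, yp = yc[(i - 1) % n], yc[i], yc[(i + 1) % n]
            if y0 >= ym and y0 > yp:
                peaks.append(_snap_to_switch(orbit, m, *_refine_extremum(orbit.ts, yc, i, tau),
                                             2.0 * dt, kind="max"))
            elif y0 <= ym and y0 < yp:
                troughs.append(_snap_to_switch(orbit, m, *_refine_extremum(orbit.ts, yc, i, tau),
                                               2.0 * dt, kind="min"))
        # drop numerically spurious ripples: keep extrema separated in level
        level_tol = 1e-9 * max(1.0, abs(mean))
        peaks = _dedupe(peaks, level_tol)
        troughs = _dedupe(troughs, level_tol)
        comps.append(
            ComponentPhases(
                name,
                sorted(peaks),
                sorted(troughs),
                flat=False,
                multi_peak=len(peaks) > 1,
            )
        )
    return PhaseSet(comps)


def _snap_to_switch(
    orbit: PeriodicOrbit, m: int, t_star: float, y_star: float, tol: float, kind: str
) -> tuple[float, float]:
    """Snap a corner extremum to the exact light-switch time.

    With square light the derivative jumps at dawn/dusk; when the one-sided
    slopes bracket zero the true extremum sits exactly at the switch, where
    a quadratic fit through grid samples lands slightly off.
    """
    if orbit.protocol.mode != "square":
        return t_star, y_star
    tau = orbit.period
    for t_b in (orbit.protocol.dawn % tau, orbit.protocol.dusk % tau):
        d = (t_star - t_b + tau / 2.0) % tau - tau / 2.0
        if abs(d) <= tol:
            before = orbit.derivative(t_b - 1e-9)[m]
            after = orbit.derivative(t_b + 1e-9)[m]
            bracket = before > 0 > after if kind == "max" else before < 0 < after
            if bracket:
                return t_b, float(orbit(t_b)[m])
    return t_star, y_star


def _dedupe(ext: list[tuple[float, float]], level_tol: float) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for t, v in sorted(ext):
        if out and abs(t - out[-1][0]) < 0.05 and abs(v - out[-1][1]) < level_tol:
            continue
        out.append((t, v))
    return out


# -- free-running period --------------------------------------------------

@dataclass
class FreeRunResult:
    period: float | None
    arrhythmic: bool
    amplitude: float
    mean_level: float
    component: str


def free_running_period(
    model: ClockModel,
    k: np.ndarray | None = None,
    light_mode: str = "DD",
    temp: TemperatureSchedule | None = None,
    T: float | None = None,
    component: int = 0,
    settle_days: float = 200.0,
    window_hours: float = 480.0,
    amplitude_floor: float = 1e-4,
    x0: np.ndarray | None = None,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
) -> FreeRunResult:
    """Estimate the free-running period in constant light (LL) or dark (DD).

    The light signal is clamped (1 in LL, 0 in DD) and the autonomous system
    is integrated for ``settle_days`` days; the period is then read from
    successive upward crossings of the observed mean level of the chosen
    component (a Poincare section).  The model is declared arrhythmic when
    the peak-to-trough amplitude falls below ``amplitude_floor`` times the
    mean level.
    """
    if light_mode not in ("LL", "DD"):
        raise ValueError("light_mode must be 'LL' or 'DD'")
    theta = 1.0 if light_mode == "LL" else 0.0
    keff = np.array(model.param_values if k is None else k, dtype=float)
    if temp is not None:
        if T is None:
            raise ValueError("constant temperature T required with a temperature schedule")
        for name, p in temp.params.items():
            keff[model.param_index(name)] = arrhenius_value(p, T)
    if len(model.light_params):
        keff[model.light_idx] = keff[model.light_idx] * model.light_scale(1.0)
    cm = model.compiled

    def f(t, y):
        return cm.rhs(y, keff, theta)

    x = np.full(model.n_states, 0.1) if x0 is None else np.asarray(x0, dtype=float)
    t_end = settle_days * 24.0
    sol = solve_ivp(f, (0.0, t_end), x, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise OrbitConvergenceError(f"free-run integration failed: {sol.message}", [])
    sol2 = solve_ivp(
        f,
        (t_end, t_end + window_hours),
        sol.y[:, -1],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    ts = np.linspace(t_end, t_end + window_hours, int(window_hours / 0.01))
    y = sol2.sol(ts)[component]
    amp = float(y.max() - y.min())
    mean = float(y.mean())
    name = model.state_names[component]
    if amp < amplitude_floor * max(abs(mean), 1e-12):
        return FreeRunResult(None, True, amp, mean, name)
    # upward crossings of the mean level, linearly interpolated
    below = y[:-1] < mean
    above = y[1:] >= mean
    idx = np.nonzero(below & above)[0]
    if len(idx) < 3:
        return FreeRunResult(None, True, amp, mean, name)
    frac = (mean - y[idx]) / (y[idx + 1] - y[idx])
    crossings = ts[idx] + frac * (ts[1] - ts[0])
    period = float(np.mean(np.diff(crossings)))
    return FreeRunResult(period, False, amp, mean, name)
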