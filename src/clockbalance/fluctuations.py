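"""Monte-Carlo simulation of daily environmental fluctuations.

Each simulated day draws either a light intensity ``alpha ~ N(mu, sigma)``
(applied from dawn to the next dawn, truncated below at zero) or a pair of
temperature offsets ``eps, eta ~ N(0, sigma_T)`` in kelvin (eps applied to
the day temperature during the lit interval, eta to the night temperature
during the dark interval).  The model is integrated continuously through the
noisy days after a deterministic transient, and per-day peak levels and peak
phases of every component are summarised by mean, standard deviation and
coefficient of variation (CV = SD/mean, population SD by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ClockModel, LightProtocol
from .orbit import (
    ATOL_DEFAULT,
    RTOL_DEFAULT,
    TemperatureSchedule,
    _integrate_segments,
    cycle_segments,
    find_entrained_orbit,
)

__all__ = [
    "FluctuationProtocol",
    "FluctuationEnsemble",
    "EnsembleStats",
    "simulate_fluctuations",
    "ensemble_statistics",
    "environmental_cv",
]


@dataclass(frozen=True)
class FluctuationProtocol:
    """Distributional settings for the daily environmental noise.

    ``kind="light"`` draws a daily light intensity alpha; ``kind=
    "temperature"`` draws daily day/night temperature offsets (kelvin) and
    requires the model call to provide a :class:`TemperatureSchedule`.
    """

    kind: str = "light"
    alpha_mean: float = 1.0
    alpha_sd: float = 0.2
    temp_sd: float = 1.0
    n_days: int = 200
    seed: int = 0
    transient_days: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("light", "temperature"):
            raise ValueError("kind must be 'light' or 'temperature'")
        if self.alpha_sd < 0 or self.temp_sd < 0 or self.n_days < 1:
            raise ValueError("invalid fluctuation settings")

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """Daily draws: column alpha for light, columns (eps, eta) for temp."""
        if self.kind == "light":
            a = rng.normal(self.alpha_mean, self.alpha_sd, size=self.n_days)
            return np.clip(a, 0.0, None)[:, None]
        return rng.normal(0.0, self.temp_sd, size=(self.n_days, 2))


@dataclass
class DayRecord:
    day: int
    draws: np.ndarray       # (alpha,) or (eps, eta)
    ts: np.ndarray          # absolute hours
    values: np.ndarray      # states x times


@dataclass
class FluctuationEnsemble:
    model: ClockModel
    protocol: LightProtocol
    fluct: FluctuationProtocol
    days: list[DayRecord]
    temp: TemperatureSchedule | None = None
    failures: list[str] = field(default_factory=list)

    @property
    def state_names(self) -> list[str]:
        return self.model.state_names

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.days:
            for m, name in enumerate(self.state_names):
                rows.append(
                    {
                        "day": rec.day,
                        "state": name,
                        "draws": tuple(np.round(rec.draws, 6)),
                        "peak_level": rec.values[m].max(),
                    }
                )
        return pd.DataFrame(rows)


def simulate_fluctuations(
    model: ClockModel,
    protocol: LightProtocol,
    fluct: FluctuationProtocol,
    temp: TemperatureSchedule | None = None,
    sample_dt: float = 0.02,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
) -> FluctuationEnsemble:
    """Integrate the model through ``n_days`` days of daily random forcing.

    The entrained orbit is converged first and a deterministic transient of
    ``transient_days`` days is integrated from it; each subsequent day runs
    dawn-to-dawn with that day's draw applied.  Failures mid-ensemble leave
    the completed days intact and are recorded in ``ensemble.failures``.
    """
    if fluct.kind == "temperature" and temp is None:
        raise ValueError("temperature fluctuations require a TemperatureSchedule")
    rng = np.random.default_rng(fluct.seed)
    draws = fluct.draw(rng)
    orbit = find_entrained_orbit(model, protocol, temp=temp, rtol=rtol, atol=atol)
    tau = protocol.period
    dawn = protocol.dawn

    # deterministic transient, dawn-aligned
    x = orbit(dawn)
    days: list[DayRecord] = []
    failures: list[str] = []
    t_abs = fluct.transient_days * tau + dawn
    n_samp = max(int(round(tau / sample_dt)), 8)
    for day, row in enumerate(draws):
        if fluct.kind == "light":
            alpha, eps, eta = float(row[0]), 0.0, 0.0
        else:
            alpha, (eps, eta) = 1.0, (float(row[0]), float(row[1]))
        segments = cycle_segments(
            model, protocol, alpha=alpha, temp=temp, eps=eps, eta=eta, t_offset=dawn
        )
        try:
            _, sols = _integrate_segments(
                model, protocol, segments, x, t_base=t_abs - dawn,
                rtol=rtol, atol=atol, dense=True,
            )
        except Exception as err:  # pragma: no cover - diagnostic path
            failures.append(f"day {day}: {err}")
            break
        ts = np.linspace(t_abs, t_abs + tau, n_samp + 1)
        vals = np.empty((model.n_states, len(ts)))
        for sol in sols:
            mask = (ts >= sol.t[0] - 1e-12) & (ts <= sol.t[-1] + 1e-12)
            if mask.any():
                vals[:, mask] = sol.sol(np.clip(ts[mask], sol.t[0], sol.t[-1]))
        x = sols[-1].y[:, -1]
        days.append(DayRecord(day=day, draws=np.asarray(row, dtype=float), ts=ts, values=vals))
        t_abs += tau
    return FluctuationEnsemble(
        model=model, protocol=protocol, fluct=fluct, days=days, temp=temp, failures=failures
    )


@dataclass
class EnsembleStats:
    """Per-component summary of daily peak levels and peak phases."""

    table: pd.DataFrame  # state, n_days, peak_mean, peak_sd, peak_cv, phase_mean, phase_sd

    def cv(self, state: str) -> float:
        return float(self.table.set_index("state").loc[state, "peak_cv"])

    def phase_sd(self, state: str) -> float:
        return float(self.table.set_index("state").loc[state, "phase_sd"])


def ensemble_statistics(
    ensemble: FluctuationEnsemble,
    transient_days: int = 0,
    sample_sd: bool = False,
) -> EnsembleStats:
    """Summarise daily peaks: level mean/SD/CV and phase mean/SD per state.

    Each day's global maximum is located on the day's samples and refined by
    a local quadratic fit; the phase is the peak time within the forcing
    cycle.  Phases are treated circularly so that peaks near the cycle
    boundary do not inflate the SD.  Population SD is the default
    (``sample_sd=True`` switches to the n-1 normalisation).
    """
    tau = ensemble.protocol.period
    ddof = 1 if sample_sd else 0
    days = [d for d in ensemble.days if d.day >= transient_days]
    if not days:
        raise ValueError("no retained days after the transient")
    rows = []
    for m, name in enumerate(ensemble.state_names):
        levels, phases = [], []
        switches = (ensemble.protocol.dawn % tau, ensemble.protocol.dusk % tau)
        for rec in days:
            y = rec.values[m]
            i = int(np.argmax(y[:-1]))
            dt = rec.ts[1] - rec.ts[0]
            at_switch = any(
                abs((rec.ts[i] - s + tau / 2) % tau - tau / 2) <= dt / 2 for s in switches
            )
            if at_switch or not 0 < i < len(y) - 1:
                # a maximum at a light switch is a corner, not a parabola:
                # a quadratic fit across the kink overshoots, so keep the sample
                t_star, y_star = rec.ts[i], y[i]
            else:
                ym, y0, yp = y[i - 1], y[i], y[i + 1]
                denom = ym - 2 * y0 + yp
                delta = 0.0 if abs(denom) < 1e-300 else float(np.clip(0.5 * (ym - yp) / denom, -1, 1))
                t_star = rec.ts[i] + delta * dt
                y_star = y0 - 0.25 * (ym - yp) * delta
            levels.append(y_star)
            phases.append(t_star % tau)
        levels = np.asarray(levels)
        phases = np.asarray(phases)
        if np.ptp(levels) == 0 and levels[0] == 0:
            rows.append(
                {"state": name, "n_days": len(days), "peak_mean": 0.0, "peak_sd": 0.0,
                 "peak_cv": np.nan, "phase_mean": np.nan, "phase_sd": np.nan}
            )
            continue
        mean = float(levels.mean())
        sd = float(levels.std(ddof=ddof))
        ph_mean, ph_sd = _circular_stats(phases, tau, ddof)
        rows.append(
            {
                "state": name,
                "n_days": len(days),
                "peak_mean": mean,
                "peak_sd": sd,
                "peak_cv": sd / mean if mean != 0 else np.nan,
                "phase_mean": ph_mean,
                "phase_sd": ph_sd,
            }
        )
    return EnsembleStats(table=pd.DataFrame(rows))


def _circular_stats(phases: np.ndarray, tau: float, ddof: int) -> tuple[float, float]:
    ang = phases * 2 * np.pi / tau
    mean_ang = np.angle(np.mean(np.exp(1j * ang)))
    # unwrap each phase to the branch nearest the circular mean
    centered = (ang - mean_ang + np.pi) % (2 * np.pi) - np.pi
    mean = (mean_ang + centered.mean()) * tau / (2 * np.pi) % tau
    sd = centered.std(ddof=ddof) * tau / (2 * np.pi)
    return float(mean), float(sd)


def environmental_cv(values, sample_sd: bool = False) -> float:
    """Coefficient of variation SD/mean of a series of daily values.

    Population SD by default; ``sample_sd=True`` uses the n-1 normalisation.
    """
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return float(v.std(ddof=1 if sample_sd else 0) / mean)
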