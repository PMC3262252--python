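"""Tabular outputs: tidy TSV exports and the temperature-compensation report."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .arrhenius import ArrheniusParam
from .model import ClockModel, LightProtocol
from .orbit import (
    PeriodicOrbit,
    PhaseSet,
    TemperatureSchedule,
    find_entrained_orbit,
    free_running_period,
    peak_phases,
)
from .sensitivity import PCDecomposition

__all__ = [
    "orbit_to_frame",
    "phases_to_frame",
    "decomposition_frames",
    "compensate_report",
    "write_tsv",
]


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def orbit_to_frame(orbit: PeriodicOrbit) -> pd.DataFrame:
    """Tidy orbit samples: columns time_h, state, value."""
    rows = {
        "time_h": np.tile(orbit.ts, orbit.model.n_states),
        "state": np.repeat(orbit.model.state_names, len(orbit.ts)),
        "value": orbit.values.ravel(),
    }
    return pd.DataFrame(rows)


def _fmt_times(pairs) -> str:
    return ", ".join(f"{t:.2f}" for t, _ in pairs)


def phases_to_frame(phases: PhaseSet) -> pd.DataFrame:
    """Phase report: one row per state, peak and trough times as lists."""
    rows = []
    for c in phases.components:
        rows.append(
            {
                "state": c.state,
                "peak_times": "undefined" if c.flat else _fmt_times(c.peaks),
                "trough_times": "undefined" if c.flat else _fmt_times(c.troughs),
                "multi_peak": c.multi_peak,
            }
        )
    return pd.DataFrame(rows)


def decomposition_frames(pc: PCDecomposition) -> dict[str, pd.DataFrame]:
    """sigma / V / W tables for export."""
    idx = [f"PC{i + 1}" for i in range(pc.n_components)]
    return {
        "sigma": pd.DataFrame({"component": idx, "sigma": pc.sigma}),
        "V": pd.DataFrame(pc.V, index=pc.param_names, columns=idx).reset_index(names="parameter"),
        "W": pd.DataFrame(pc.W, index=idx, columns=pc.param_names).reset_index(names="component"),
    }


def compensate_report(
    model: ClockModel,
    arrhenius: dict[str, ArrheniusParam],
    T_grid,
    protocol: LightProtocol | None = None,
    free_running: bool = False,
    light_mode: str = "LL",
    **orbit_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Entrained peak/trough times per temperature, plus free-running periods.

    For each temperature on the grid the temperature-sensitive parameters
    are set by their Arrhenius laws (day and night temperature equal, so the
    only forcing is light), the entrained orbit is converged and peak and
    trough times are tabulated.  With ``free_running=True`` a second table
    holds the constant-condition period per temperature (None where the
    model is arrhythmic at that temperature).
    """
    protocol = protocol if protocol is not None else LightProtocol(period=model.forcing_period)
    phase_rows, period_rows = [], []
    for T in np.atleast_1d(np.asarray(T_grid, dtype=float)):
        temp = TemperatureSchedule(params=arrhenius, T_day=float(T), T_night=float(T))
        orbit = find_entrained_orbit(model, protocol, temp=temp, **orbit_kwargs)
        phases = peak_phases(orbit)
        for c in phases.components:
            phase_rows.append(
                {
                    "T_kelvin": float(T),
                    "state": c.state,
                    "peak_times": "undefined" if c.flat else _fmt_times(c.peaks),
                    "trough_times": "undefined" if c.flat else _fmt_times(c.troughs),
                    "peak_time": c.peak_time,
                    "trough_time": c.trough_time,
                }
            )
        if free_running:
            res = free_running_period(model, temp=temp, T=float(T), light_mode=light_mode)
            period_rows.append(
                {
                    "T_kelvin": float(T),
                    "period_h": res.period,
                    "arrhythmic": res.arrhythmic,
                    "amplitude": res.amplitude,
                }
            )
    return pd.DataFrame(phase_rows), (pd.DataFrame(period_rows) if free_running else None)
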