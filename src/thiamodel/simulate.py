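"""Time-course simulation of dC/dt = N · v(C) as a stiff ODE system.

The integrator is LSODA (adaptive stiff/non-stiff switching, via
``scipy.integrate.solve_ivp``) with tight defaults suited to nmol/L-scale
dynamics.  Output is reported on a uniform time grid evaluated from the
solver's dense interpolant, so refining the grid never re-integrates.

Plateau detection follows a trailing-window flatness rule: the quasi-steady
level is declared reached when the maximum relative variation over the last
``plateau_window`` fraction of the course falls below ``plateau_slope_tol``.
The plateau value is reported both as the window mean and as the terminal
value (the two coincide for a true plateau).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import PathwayModel
from .rates import IntegrationStateError, RateEvaluator

__all__ = [
    "SimulationConfig",
    "TimeCourseResult",
    "SimulationError",
    "simulate",
    "detect_plateau",
    "find_peak",
    "format_time",
]


class SimulationError(RuntimeError):
    """Integration failure with a diagnostic naming metabolite and time."""


@dataclass
class SimulationConfig:
    """Simulation horizon, output grid and numerical tolerances.

    t_end
        duration in seconds; the default 10_000 s (2 h 47 min) is long enough
        for the thiamin network to form its plateau.
    n_output_points
        size of the uniform reporting grid (includes t=0).
    rel_tol / abs_tol
        LSODA tolerances; abs_tol is in nmol/L.
    plateau_window / plateau_slope_tol
        trailing fraction of the course inspected for flatness, and the
        relative-variation threshold under which a plateau is declared.
    """

    t_end: float = 10_000.0
    n_output_points: int = 1000
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12
    plateau_window: float = 0.1
    plateau_slope_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.n_output_points < 2:
            raise ValueError("n_output_points must be >= 2")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0 < self.plateau_window < 1:
            raise ValueError("plateau_window must be in (0, 1)")


def detect_plateau(
    times: Sequence[float],
    values: Sequence[float],
    config: SimulationConfig | None = None,
) -> tuple[bool, float | None]:
    """Trailing-window flatness test.

    Returns ``(reached, value)`` where *value* is the mean over the trailing
    window (None when no plateau).  Reached iff the maximum relative change
    across the window, ``(max-min)/max(|mean|, abs_tol)``, is below
    ``plateau_slope_tol``.
    """
    config = config or SimulationConfig()
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and equally long")
    if len(t) < 10:
        raise ValueError("need at least 10 output points for plateau detection")
    n_win = max(2, int(np.ceil(config.plateau_window * len(t))))
    tail = y[-n_win:]
    mean = float(tail.mean())
    spread = float(tail.max() - tail.min())
    scale = max(abs(mean), config.abs_tol)
    if spread / scale < config.plateau_slope_tol:
        return True, mean
    return False, None


def find_peak(times: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    """Global maximum on the output grid, refined by quadratic interpolation.

    Fits a parabola through the maximal grid point and its neighbours; ties
    break toward the earliest time.  Endpoint maxima are returned as-is.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) == 0:
        raise ValueError("empty series")
    i = int(np.argmax(y))  # argmax returns the first maximum: earliest tie wins
    if i == 0 or i == len(t) - 1:
        return float(t[i]), float(y[i])
    t0, t1, t2 = t[i - 1 : i + 2]
    y0, y1, y2 = y[i - 1 : i + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0:  # flat or non-concave triple; keep the grid point
        return float(t1), float(y1)
    # uniform-grid quadratic vertex
    h = (t2 - t0) / 2.0
    delta = 0.5 * (y0 - y2) / denom
    t_peak = t1 + delta * h
    y_peak = y1 - 0.25 * (y0 - y2) * delta
    return float(t_peak), float(y_peak)


def format_time(seconds: float) -> str:
    """Render seconds as a human-readable "Xm Ys" (or "Xh Ym Zs") string."""
    s = int(round(seconds))
    h, rem = divmod(s, 3600)
    m, sec = divmod(rem, 60)
    if h:
        return f"{h}h {m}m {sec}s"
    return f"{m}m {sec}s"


@dataclass
class TimeCourseResult:
    """Uniform time grid plus the concentration trajectory of every metabolite."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_metabolites, n_times)
    metabolite_ids: list[str]
    config: SimulationConfig
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {m: i for i, m in enumerate(self.metabolite_ids)}

    def series(self, metabolite_id: str) -> np.ndarray:
        return self.concentrations[self._index[metabolite_id]]

    def final_value(self, metabolite_id: str) -> float:
        return float(self.series(metabolite_id)[-1])

    def peak(self, metabolite_id: str) -> tuple[float, float]:
        return find_peak(self.times, self.series(metabolite_id))

    def plateau_reached(self, metabolite_id: str) -> tuple[bool, float | None]:
        return detect_plateau(self.times, self.series(metabolite_id), self.config)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, metabolite_id, concentration) frame."""
        n_t = len(self.times)
        return pd.DataFrame(
            {
                "time": np.tile(self.times, len(self.metabolite_ids)),
                "metabolite_id": np.repeat(self.metabolite_ids, n_t),
                "concentration": self.concentrations.reshape(-1),
            }
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def simulate(model: PathwayModel, config: SimulationConfig | None = None) -> TimeCourseResult:
    """Integrate the model's ODE system over ``[0, t_end]``.

    Clamped (boundary) species are held at their initial concentration by
    zeroing their derivative.  Deterministic for a given model and config.
    Raises :class:`SimulationError` naming the first offending metabolite and
    time on integration failure.
    """
    config = config or SimulationConfig()
    evaluator = RateEvaluator(model)

    n_m = model.n_metabolites
    stoich = np.zeros((n_m, model.n_reactions))
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            stoich[model.metabolite_index(met_id), j] = coeff
    free = np.array([not m.boundary for m in model.metabolites])

    state: dict = {"t": 0.0}

    def rhs(t: float, c: np.ndarray) -> np.ndarray:
        state["t"] = t
        dc = stoich @ evaluator(c)
        dc[~free] = 0.0
        return dc

    c0 = np.asarray(model.initial_state(), dtype=float)
    t_eval = np.linspace(0.0, config.t_end, config.n_output_points)
    try:
        sol = solve_ivp(
            rhs,
            (0.0, config.t_end),
            c0,
            method="LSODA",
            t_eval=t_eval,
            rtol=config.rel_tol,
            atol=config.abs_tol,
        )
    except IntegrationStateError as exc:
        raise SimulationError(f"integration failed near t={state['t']:.6g} s: {exc}") from exc
    if not sol.success:
        raise SimulationError(
            f"integration failed near t={state['t']:.6g} s: {sol.message}"
        )
    conc = sol.y
    if not np.all(np.isfinite(conc)):
        i, j = np.argwhere(~np.isfinite(conc))[0]
        raise SimulationError(
            f"non-finite concentration for {model.metabolite_ids[int(i)]} at "
            f"t={sol.t[int(j)]:.6g} s"
        )
    # solver excursions below zero are cosmetic at abs_tol scale; clamp for reporting
    conc = np.maximum(conc, 0.0)
    conc[~free] = c0[~free][:, None]
    return TimeCourseResult(
        times=sol.t, concentrations=conc, metabolite_ids=model.metabolite_ids, config=config
    )
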