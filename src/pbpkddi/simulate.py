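"""Event-driven multiple-dose integration of the PBPK system.

Oral doses enter the stomach compartment instantaneously at their event
times; between events the system is integrated with a stiff-capable solver
(LSODA) at tight tolerances.  Output is reported on a dense, regular time
grid plus every event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import core
from .core import N_STATE, IDX, DrugModel, JointModel, PathwayMask
from .params import (DrugParams, InhibitionParams, PhysioParams, MG_TO_NG,
                     load_inhibition, load_physiology)


class SolverError(RuntimeError):
    pass


@dataclass
class DoseRegimen:
    """Oral dosing schedule: (time_min, dose_mg) events, nondecreasing times."""

    events: list
    lag_min: float = 0.0

    def __post_init__(self):
        times = [t for t, _ in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose event times must be nondecreasing")
        if any(d <= 0 for _, d in self.events):
            raise ValueError("doses must be positive")

    @classmethod
    def single(cls, dose_mg: float, time_min: float = 0.0, lag_min: float = 0.0):
        return cls(events=[(time_min, dose_mg)], lag_min=lag_min)

    @classmethod
    def repeated(cls, dose_mg: float, interval_h: float, n: int,
                 start_min: float = 0.0, lag_min: float = 0.0):
        return cls(events=[(start_min + i * interval_h * 60.0, dose_mg)
                           for i in range(n)], lag_min=lag_min)

    @classmethod
    def qd(cls, dose_mg: float, days: int, start_min: float = 0.0):
        return cls.repeated(dose_mg, 24.0, days, start_min)

    @classmethod
    def bid(cls, daily_dose_mg: float, days: int, start_min: float = 0.0):
        return cls.repeated(daily_dose_mg / 2.0, 12.0, 2 * days, start_min)

    def effective_events(self) -> list:
        return [(t + self.lag_min, d) for t, d in self.events]

    @property
    def last_time(self) -> float:
        return max(t for t, _ in self.effective_events())


@dataclass
class ConcentrationProfile:
    """Dense simulated profile for one drug (time in min, conc in ng/mL)."""

    time_min: np.ndarray
    blood_ngml: np.ndarray
    rb: float
    amounts: pd.DataFrame
    dose_mg_total: float

    @property
    def time_h(self) -> np.ndarray:
        return self.time_min / 60.0

    @property
    def plasma_ngml(self) -> np.ndarray:
        return self.blood_ngml / self.rb

    def concentration(self, matrix: str = "plasma") -> np.ndarray:
        if matrix == "plasma":
            return self.plasma_ngml
        if matrix == "blood":
            return self.blood_ngml
        raise ValueError("matrix must be 'plasma' or 'blood'")

    def to_frame(self, include_amounts: bool = False) -> pd.DataFrame:
        df = pd.DataFrame({"time_min": self.time_min,
                           "blood_ngml": self.blood_ngml,
                           "plasma_ngml": self.plasma_ngml})
        if include_amounts:
            df = pd.concat([df, self.amounts.reset_index(drop=True)], axis=1)
        return df

    def mass_balance_error(self) -> float:
        """Max relative deviation of (compartments + sinks) from dose given."""
        total = self.amounts.sum(axis=1).to_numpy()
        dosed = np.array([self._dose_given_by(t) for t in self.time_min])
        live = dosed > 0
        return float(np.max(np.abs(total[live] - dosed[live]) / dosed[live])) if live.any() else 0.0

    def _attach_events(self, events):
        self._events_ng = [(t, d * MG_TO_NG) for t, d in events]

    def _dose_given_by(self, t: float) -> float:
        return sum(d for te, d in self._events_ng if te <= t + 1e-9)


@dataclass
class SimulationResult:
    victim: ConcentrationProfile
    inhibitor: Optional[ConcentrationProfile] = None


def _output_grid(t_end: float, step: float, event_times) -> np.ndarray:
    grid = np.arange(0.0, t_end + 0.5 * step, step)
    grid = np.union1d(grid, np.asarray(sorted(event_times)))
    return grid[grid <= t_end + 1e-9]


def run(drug: DrugParams, regimen: DoseRegimen,
        physio: Optional[PhysioParams] = None,
        inhibitor: Optional[DrugParams] = None,
        inhibitor_regimen: Optional[DoseRegimen] = None,
        *,
        inhibition: Optional[InhibitionParams] = None,
        pathway_mask: Optional[PathwayMask] = None,
        disabled_inhibition: frozenset = frozenset(),
        duration_min: Optional[float] = None,
        output_step_min: float = 2.0,
        rtol: float = 1e-8, atol: float = 1e-6,
        method: str = "LSODA") -> SimulationResult:
    """Simulate one drug, optionally co-dosed with a perpetrator.

    Returns dense concentration profiles (<= ``output_step_min`` spacing) for
    the victim and, when co-simulated, the perpetrator.  Deterministic for
    given inputs.
    """
    physio = physio or load_physiology()
    lag = drug.lag_time or 0.0
    if lag and regimen.lag_min == 0.0:
        regimen = DoseRegimen(events=regimen.events, lag_min=lag)

    joint = inhibitor is not None
    if joint:
        if inhibitor_regimen is None:
            raise ValueError("inhibitor_regimen required when an inhibitor is supplied")
        inhibition = inhibition or load_inhibition()
        victim_model = DrugModel(drug, physio, inhibition=inhibition,
                                 pathway_mask=pathway_mask,
                                 disabled_inhibition=disabled_inhibition)
        inhibitor_model = DrugModel(inhibitor, physio)  # no self-inhibition
        model = JointModel(victim_model, inhibitor_model)
        fun = lambda t, y: model.rhs(y)
        n = model.n
    else:
        victim_model = DrugModel(drug, physio, pathway_mask=pathway_mask)
        fun = lambda t, y: victim_model.rhs(y)
        n = N_STATE

    victim_events = regimen.effective_events()
    inhibitor_events = inhibitor_regimen.effective_events() if joint else []
    dose_map = {}
    for t, d in victim_events:
        dose_map.setdefault(t, np.zeros(n))[IDX["stomach"]] += d * MG_TO_NG
    for t, d in inhibitor_events:
        dose_map.setdefault(t, np.zeros(n))[N_STATE + IDX["stomach"]] += d * MG_TO_NG

    last_event = max(t for t in dose_map)
    t_end = duration_min if duration_min is not None else last_event + 48.0 * 60.0
    if t_end <= 0:
        raise ValueError("simulation duration must be positive")
    grid = _output_grid(t_end, output_step_min, [t for t in dose_map if t <= t_end])

    breakpoints = sorted({0.0, t_end, *[t for t in dose_map if t < t_end]})
    y = np.zeros(n)
    times, states = [], []
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        if t0 in dose_map:
            y = y + dose_map[t0]
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        if t_eval.size == 0 or t_eval[0] > t0:
            t_eval = np.insert(t_eval, 0, t0)
        if t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(fun, (t0, t1), y, method=method, t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverError(
                f"integration failed at t={sol.t[-1] if sol.t.size else t0:.2f} min: "
                f"{sol.message}")
        if sol.y.min() < -1e-9 * max(1.0, np.abs(sol.y).max()):
            raise SolverError("solver produced significantly negative amounts")
        # at event times report the post-dose state: replace the previous
        # segment's endpoint with this segment's (dosed) start
        if times and abs(times[-1] - sol.t[0]) < 1e-9:
            times.pop()
            states[-1] = states[-1][:, :-1]
        times.extend(sol.t)
        states.append(sol.y)
        y = sol.y[:, -1]
    t_arr = np.asarray(times)
    y_arr = np.concatenate(states, axis=1)

    def make_profile(block: np.ndarray, d: DrugParams, events) -> ConcentrationProfile:
        amounts = pd.DataFrame(np.clip(block.T, 0.0, None), columns=core.STATE_NAMES)
        blood = np.clip(block[IDX["venous"], :] / physio.tissue_volumes["venous"], 0.0, None)
        prof = ConcentrationProfile(time_min=t_arr, blood_ngml=blood, rb=d.rb,
                                    amounts=amounts,
                                    dose_mg_total=sum(dd for _, dd in events))
        prof._attach_events(events)
        return prof

    victim_prof = make_profile(y_arr[:N_STATE], drug, victim_events)
    inhibitor_prof = (make_profile(y_arr[N_STATE:], inhibitor, inhibitor_events)
                      if joint else None)
    return SimulationResult(victim=victim_prof, inhibitor=inhibitor_prof)
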