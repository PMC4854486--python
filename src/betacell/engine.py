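"""Stiff integration with timed step events, and steady-state search.

Stimulation protocols are expressed as an :class:`EventSchedule`: an ordered
list of (time, target, value) steps, where a target is either an external
input (Glu, FFA, GLP1, GIP, AR3, AM3, AR7) or a parameter name (g_mKATP,
g_mNM3, ATD_m, V_cpde, k_ipde, V_mPLP, receptor totals, ...).  Events are
integration breakpoints: the solver is restarted with the updated inputs or
parameter set, which reproduces the exact discontinuity of the step terms
without asking the solver to integrate through them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import model
from .params import ParameterSet, UnitContext, load_parameters

__all__ = [
    "Event",
    "ScenarioConfig",
    "Trajectory",
    "SteadyStateResult",
    "integrate",
    "find_steady_state",
    "export_trajectory",
]

_DEFAULT_RTOL = 1e-8
# per-variable absolute tolerance scales: species spanning 1e-3..1e5 need
# individual floors for the stiff solver to be efficient
_ATOL_SCALES = {
    "ATD": 1e-8, "Vp": 1e-7,
    "CaCaM": 1e-10, "cAMP": 1e-10, "PKAa": 1e-10, "EPa": 1e-10,
    "P4P": 1e-5, "PIP2": 1e-5, "IP3": 1e-10, "DAG": 1e-7, "PKCa": 1e-10,
    "Cac": 1e-11, "CaER": 1e-7,
}


def _atol_vector() -> np.ndarray:
    return np.array([_ATOL_SCALES.get(name, 1e-10) for name in model.STATE_NAMES])


@dataclass(frozen=True)
class Event:
    """A step change applied at ``time``: input or parameter ``target`` is
    set to ``value`` for the rest of the run (until a later event)."""
    time: float
    target: str
    value: float


@dataclass
class ScenarioConfig:
    """Everything needed to run one in-silico experiment."""
    name: str = "custom"
    overrides: dict[str, float] = field(default_factory=dict)
    inputs: dict[str, float] = field(default_factory=dict)  # initial inputs
    events: list[Event] = field(default_factory=list)
    duration: float = 1000.0
    sample_dt: float = 1.0
    rtol: float = _DEFAULT_RTOL
    steady_state_first: bool = True
    initial_state: np.ndarray | None = None

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.sample_dt <= 0 or self.sample_dt > self.duration:
            raise ValueError("sample_dt must be in (0, duration]")
        times = [e.time for e in self.events]
        if any(t < 0 for t in times):
            raise ValueError("event times must be >= 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")


@dataclass
class Trajectory:
    """Sampled time series of states and recomputed derived quantities."""
    time: np.ndarray
    states: pd.DataFrame          # columns = STATE_NAMES
    derived: pd.DataFrame         # columns = DERIVED_NAMES
    events: list[Event]
    config: ScenarioConfig

    def __getitem__(self, name: str) -> np.ndarray:
        if name in self.states.columns:
            return self.states[name].to_numpy()
        return self.derived[name].to_numpy()

    def final_state(self) -> np.ndarray:
        return self.states.iloc[-1].to_numpy()

    def value_at(self, name: str, t: float) -> float:
        i = int(np.searchsorted(self.time, t, side="right") - 1)
        return float(self[name][max(i, 0)])


@dataclass
class SteadyStateResult:
    state: np.ndarray
    inputs: dict[str, float]
    residual: float               # max scaled |dx/dt|
    time_integrated: float
    converged: bool
    oscillatory: bool = False

    def __getitem__(self, name: str) -> float:
        return float(self.state[model.STATE_INDEX[name]])

    def derived(self, p: ParameterSet) -> dict[str, float]:
        return model.derived_quantities(self.state, self.inputs, p)


class SolverError(RuntimeError):
    def __init__(self, message: str, t: float, y: np.ndarray):
        super().__init__(f"{message} (last good state at t={t:.1f} s)")
        self.t = t
        self.y = y


def _apply_event(event: Event, inputs: dict[str, float],
                 p: ParameterSet) -> tuple[dict[str, float], ParameterSet]:
    if event.target in model.INPUT_NAMES:
        inputs = dict(inputs)
        inputs[event.target] = float(event.value)
        return inputs, p
    return inputs, p.with_overrides({event.target: event.value})


def _integrate_segment(t0: float, t1: float, y0: np.ndarray,
                       inputs: Mapping[str, float], p: ParameterSet,
                       ctx: UnitContext, rtol: float,
                       t_eval: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    sol = solve_ivp(
        model.assemble_derivatives, (t0, t1), y0, method="BDF",
        t_eval=t_eval, args=(inputs, p, ctx),
        rtol=rtol, atol=_atol_vector())
    if not sol.success:
        raise SolverError(f"stiff solver failed: {sol.message}",
                          float(sol.t[-1]) if len(sol.t) else t0,
                          sol.y[:, -1] if sol.y.size else y0)
    return sol.t, sol.y


def integrate(config: ScenarioConfig,
              p: ParameterSet | None = None) -> Trajectory:
    """Run a scenario and return the sampled trajectory.

    With ``steady_state_first`` (the default, matching the equilibrate-then-
    stimulate protocol of the in-silico experiments) the model is first
    relaxed to steady state at the scenario's initial inputs, and t=0 of the
    trajectory starts from that rest state.
    """
    config.validate()
    if p is None:
        p = load_parameters(config.overrides)
    elif config.overrides:
        p = p.with_overrides(config.overrides)
    ctx = UnitContext.from_parameters(p)

    inputs = model.default_inputs(p)
    inputs.update(config.inputs)

    if config.initial_state is not None:
        y = np.asarray(config.initial_state, dtype=float).copy()
    else:
        y = model.table_initial_state(p)
    if config.steady_state_first:
        ss = find_steady_state(p, inputs, from_state=y)
        y = ss.state

    grid = np.arange(0.0, config.duration + 0.5 * config.sample_dt,
                     config.sample_dt)
    grid[-1] = min(grid[-1], config.duration)

    breakpoints = ([0.0]
                   + [e.time for e in config.events if 0.0 < e.time < config.duration]
                   + [config.duration])
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    cur_p = p
    cur_inputs = dict(inputs)
    pending = list(config.events)
    # events at t=0 apply before integration starts
    while pending and pending[0].time <= 0.0:
        cur_inputs, cur_p = _apply_event(pending.pop(0), cur_inputs, cur_p)

    for t0, t1 in zip(breakpoints, breakpoints[1:]):
        seg_grid = grid[(grid >= t0) & (grid <= t1)]
        t_eval = seg_grid if len(seg_grid) else None
        ts, ys = _integrate_segment(t0, t1, y, cur_inputs, cur_p, ctx,
                                    config.rtol, t_eval)
        # endpoint state for continuation even if not on the sample grid
        _, y_end = _integrate_segment(ts[-1], t1, ys[:, -1], cur_inputs,
                                      cur_p, ctx, config.rtol, None) \
            if ts[-1] < t1 else (None, ys[:, [-1]])
        if len(ts):
            # avoid duplicating the shared breakpoint sample
            if times and len(ts) and ts[0] == times[-1][-1]:
                ts, ys = ts[1:], ys[:, 1:]
            if len(ts):
                times.append(ts)
                states.append(ys)
        y = y_end[:, -1]
        while pending and pending[0].time <= t1:
            cur_inputs, cur_p = _apply_event(pending.pop(0), cur_inputs, cur_p)

    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=1).T
    y_all = np.where((y_all < 0) & (np.abs(y_all) < 1e-12), 0.0, y_all)

    # derived quantities recomputed per sample with the then-active
    # inputs/parameters
    seg_p, seg_inputs = p, dict(inputs)
    ev = sorted(config.events, key=lambda e: e.time)
    derived_rows = []
    j = 0
    for t, ystate in zip(t_all, y_all):
        while j < len(ev) and ev[j].time <= t:
            seg_inputs, seg_p = _apply_event(ev[j], seg_inputs, seg_p)
            j += 1
        model.check_closures(ystate, seg_p)
        derived_rows.append(model.derived_quantities(ystate, seg_inputs, seg_p, ctx))

    return Trajectory(
        time=t_all,
        states=pd.DataFrame(y_all, columns=list(model.STATE_NAMES)),
        derived=pd.DataFrame(derived_rows, columns=list(model.DERIVED_NAMES)),
        events=list(config.events),
        config=config,
    )


# characteristic relaxation times used to scale steady-state residuals: a
# residual is "small" when |dx/dt|·tau is well below the variable's scale
_SS_CHUNK = 2000.0
_SS_TOL = 1e-7      # max |dx/dt| / scale(x), per second
_SS_CAP = 50000.0


def _scaled_residual(dy: np.ndarray, y: np.ndarray) -> float:
    scale = np.maximum(np.abs(y), _atol_vector() * 1e3 + 1e-6)
    return float(np.max(np.abs(dy) / scale))


def find_steady_state(p: ParameterSet, inputs: Mapping[str, float] | None = None,
                      from_state: np.ndarray | None = None,
                      tol: float = _SS_TOL, t_cap: float = _SS_CAP,
                      rtol: float = _DEFAULT_RTOL) -> SteadyStateResult:
    """Relax the model to steady state at fixed inputs.

    Integrates in chunks until the scaled derivative norm falls below
    ``tol`` (fractional change per second), then polishes with a Newton
    solve; the Newton solution is accepted only if it stays non-negative and
    close to the integrated state.  If the cap ``t_cap`` is reached without
    convergence, the result carries ``converged=False`` and (if the
    trajectory is cycling) ``oscillatory=True`` with a time-averaged state.
    """
    ctx = UnitContext.from_parameters(p)
    full_inputs = model.default_inputs(p)
    if inputs:
        full_inputs.update(inputs)
    y = (model.table_initial_state(p) if from_state is None
         else np.asarray(from_state, dtype=float).copy())

    def residual_at(z):
        dz = model.assemble_derivatives(0.0, z, full_inputs, p, ctx)
        return _scaled_residual(dz, z)

    t = 0.0
    window: list[np.ndarray] = []
    while t < t_cap:
        _, ys = _integrate_segment(t, t + _SS_CHUNK, y, full_inputs, p, ctx,
                                   rtol, None)
        y = ys[:, -1]
        t += _SS_CHUNK
        window.append(y.copy())
        if len(window) > 5:
            window.pop(0)
        residual = residual_at(y)
        if residual < tol:
            break
        # once the fast dynamics have settled, a Newton solve removes the
        # slow receptor-recycling tail (time constant 1/k_8n ~ 2e4 s)
        if t >= 3 * _SS_CHUNK and residual < 1e-3:
            polished = _newton_polish(y, full_inputs, p, ctx)
            if polished is not None and residual_at(polished) < tol:
                return SteadyStateResult(state=polished,
                                         inputs=dict(full_inputs),
                                         residual=residual_at(polished),
                                         time_integrated=t, converged=True)
    else:
        # non-convergence: report a time-averaged state over the last window
        avg = np.mean(window, axis=0)
        spread = _scaled_residual(np.ptp(window, axis=0), avg)
        return SteadyStateResult(state=avg, inputs=dict(full_inputs),
                                 residual=residual_at(avg),
                                 time_integrated=t, converged=False,
                                 oscillatory=spread > 10 * tol)

    polished = _newton_polish(y, full_inputs, p, ctx)
    if polished is not None:
        y = polished
    return SteadyStateResult(state=y, inputs=dict(full_inputs),
                             residual=residual_at(y), time_integrated=t,
                             converged=True)


def _newton_polish(y: np.ndarray, inputs: Mapping[str, float],
                   p: ParameterSet, ctx: UnitContext) -> np.ndarray | None:
    """Newton solve of the full RHS near ``y``; returns the root only if it
    is non-negative and stays close to the integrated state (no jump to a
    different fixed point)."""
    scale = np.maximum(np.abs(y), 1e-6)

    def fun(z):
        return model.assemble_derivatives(0.0, z * scale, inputs, p, ctx)

    try:
        sol = root(fun, y / scale, method="hybr", tol=1e-12)
    except (ValueError, FloatingPointError):
        return None
    if not sol.success:
        return None
    z = sol.x * scale
    is_vp = np.array([name == "Vp" for name in model.STATE_NAMES])
    nonneg_ok = np.all(z[~is_vp] > -1e-9)
    close = np.all(np.abs(z - y) <= 0.3 * scale + 1e-6)
    vp_close = abs(z[is_vp][0] - y[is_vp][0]) < 5.0
    if nonneg_ok and close and vp_close:
        z = z.copy()
        z[~is_vp] = np.maximum(z[~is_vp], 0.0)
        return z
    return None


def export_trajectory(traj: Trajectory, path, fmt: str = "csv") -> None:
    """Write a trajectory to CSV (flat table) or JSON (table + metadata)."""
    table = pd.concat(
        [pd.Series(traj.time, name="time"), traj.states, traj.derived], axis=1)
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "json":
        payload = {
            "scenario": traj.config.name,
            "overrides": traj.config.overrides,
            "events": [[e.time, e.target, e.value] for e in traj.events],
            "columns": list(table.columns),
            "rows": table.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
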