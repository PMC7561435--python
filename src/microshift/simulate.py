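"""Scenario integration with event handling.

The mass-balance system is stiff in places (Monod terms with small
saturation constants, steep logistic switches), so integration uses
SciPy's adaptive stiff-capable solvers, segmented at every known
discontinuity: the end of the lag phase, each feeding-phase boundary and
each glucose pulse.  The discontinuous death switch is handled exactly by
root-finding on ``[P] - tau``: within a segment the switch is held fixed
and an integrator event locates the crossing, where integration restarts
with the switch flipped.

Alongside the 8 physical states an auxiliary quadrature state accumulates
the glucose uptake flux, so mass-balance audits (glucose fed versus
consumed) are accurate to integrator tolerance rather than to the output
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .feeding import FeedingSchedule, apply_pulse, feed_rate
from .model import (
    DEFAULT_OPTIONS,
    STATE_FIELDS,
    ModelOptions,
    ReactorState,
    StrainParameters,
    derive,
    process_rates,
    rhs,
)

__all__ = [
    "Scenario",
    "Trajectory",
    "Observables",
    "SimulationError",
    "simulate",
    "observables",
    "max_specific_growth_rate",
]


class SimulationError(RuntimeError):
    """Integration failed; carries the last successfully reached state."""

    def __init__(self, message: str, t: float | None = None, state=None):
        super().__init__(message)
        self.t = t
        self.last_state = state


@dataclass(frozen=True)
class Scenario:
    """Everything needed to run one culture: initial state, schedule, strain."""

    initial_state: ReactorState
    schedule: FeedingSchedule
    params: StrainParameters
    t0: float = 0.0
    t_lag: float = 0.0
    options: ModelOptions = DEFAULT_OPTIONS
    name: str = ""

    def __post_init__(self) -> None:
        self.initial_state.validate()
        if any(getattr(self.initial_state, f) < 0 for f in STATE_FIELDS):
            raise ValueError("initial stocks must be non-negative")
        if self.t_end <= self.t0:
            raise ValueError("t_end must exceed t0")

    @property
    def t_end(self) -> float:
        return self.schedule.t_end


@dataclass
class Trajectory:
    """Dense solution: states, derived quantities and process rates per time."""

    times: np.ndarray              # (n,) hours, strictly increasing
    states: np.ndarray             # (n, 8) in STATE_FIELDS order
    cumulative_uptake: np.ndarray  # (n,) grams of glucose taken up since t0
    scenario: Scenario

    def state_at(self, i: int) -> ReactorState:
        return ReactorState.from_array(self.states[i])

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]

    @property
    def derived(self) -> list:
        sc = self.scenario
        return [
            derive(self.state_at(i), sc.params, float(t), sc.t_lag, sc.options)
            for i, t in enumerate(self.times)
        ]

    @property
    def rates(self) -> list:
        sc = self.scenario
        out = []
        for i, t in enumerate(self.times):
            st = self.state_at(i)
            dq = derive(st, sc.params, float(t), sc.t_lag, sc.options)
            out.append(process_rates(dq, st, sc.params, options=sc.options))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a table with the standard CSV column schema."""
        sc = self.scenario
        obs = observables(self)
        df = pd.DataFrame({
            "time_h": self.times,
            "G_g": self.column("G"),
            "P_g": self.column("P"),
            "A_g": self.column("A"),
            "CM_g": self.column("C_M"),
            "R_g": self.column("R"),
            "I_g": self.column("I"),
            "D_g": self.column("D"),
            "V_L": self.column("V"),
            "biomass_gL": obs.biomass_conc,
            "glucose_gL": obs.glucose_conc,
            "acetate_gL": obs.acetate_conc,
        })
        return df


@dataclass
class Observables:
    """The measurable outputs: concentrations (g/L) and specific growth rate."""

    times: np.ndarray
    biomass_conc: np.ndarray
    glucose_conc: np.ndarray
    acetate_conc: np.ndarray
    specific_growth_rate: np.ndarray  # d(ln living mass)/dt, 1/h

    def series(self, output: str) -> np.ndarray:
        return {
            "biomass": self.biomass_conc,
            "glucose": self.glucose_conc,
            "acetate": self.acetate_conc,
        }[output]


_MAX_SWITCH_FLIPS = 200


def _integrate_segment(
    y0: np.ndarray,
    t_a: float,
    t_b: float,
    scenario: Scenario,
    grid: np.ndarray,
    rtol: float,
    atol: float,
    method: str,
):
    """Integrate over [t_a, t_b] (no feed discontinuities inside).

    Returns (times, states) sampled on `grid` plus segment endpoints and
    death-switch crossing times, and the final state vector.
    """
    sc = scenario
    params = sc.params

    def f(t, y):
        # tiny negative excursions are integration noise; rates see them as 0,
        # so the clamped-rate design (no flux from an empty stock) self-corrects
        st = ReactorState.from_array(np.maximum(y[:8], 0.0))
        fv, fg = feed_rate(min(max(t, sc.schedule.t_start), sc.t_end), sc.schedule)
        deriv, r = rhs(t, st, params, fv, fg, sc.t_lag, f.death_active, sc.options)
        return deriv + [r.uptake]

    def pconc_minus_tau(t, y):
        st = ReactorState.from_array(y)
        BR = st.P + st.C_M + st.R
        pc = st.P / (BR * params.c) if BR > 0 else 0.0
        return pc - params.tau

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []

    st0 = ReactorState.from_array(y0)
    BR0 = st0.P + st0.C_M + st0.R
    pc0 = st0.P / (BR0 * params.c) if BR0 > 0 else 0.0
    death = 1.0 if pc0 > params.tau else 0.0

    t_cur, y_cur = t_a, np.asarray(y0, dtype=float)
    for _ in range(_MAX_SWITCH_FLIPS):
        f.death_active = None if sc.options.smooth_death_switch else death
        pconc_minus_tau.terminal = True
        pconc_minus_tau.direction = 1.0 if death == 0.0 else -1.0
        inner = grid[(grid > t_cur) & (grid < t_b)]
        t_eval = np.unique(np.concatenate([[t_cur], inner, [t_b]]))
        events = None if sc.options.smooth_death_switch else [pconc_minus_tau]
        sol = solve_ivp(
            f, (t_cur, t_b), y_cur, method=method, t_eval=t_eval,
            events=events, rtol=rtol, atol=atol, dense_output=False,
        )
        if not sol.success:
            raise SimulationError(
                f"integrator failed in [{t_cur}, {t_b}]: {sol.message}",
                t=float(sol.t[-1]) if sol.t.size else t_cur,
                state=ReactorState.from_array(sol.y[:, -1]) if sol.t.size else None,
            )
        crossed = events is not None and sol.t_events[0].size > 0
        if crossed:
            t_ev = float(sol.t_events[0][0])
            y_ev = sol.y_events[0][0]
            keep = sol.t < t_ev
            times_out.append(sol.t[keep])
            states_out.append(sol.y[:, keep].T)
            times_out.append(np.array([t_ev]))
            states_out.append(y_ev[None, :])
            t_cur, y_cur = t_ev, np.asarray(y_ev, dtype=float)
            death = 1.0 - death
            if t_cur >= t_b:
                break
        else:
            times_out.append(sol.t)
            states_out.append(sol.y.T)
            t_cur, y_cur = t_b, sol.y[:, -1].copy()
            break
    else:
        raise SimulationError(
            f"death switch chattering: > {_MAX_SWITCH_FLIPS} crossings in "
            f"[{t_a}, {t_b}]"
        )
    return np.concatenate(times_out), np.vstack(states_out), y_cur


def simulate(
    scenario: Scenario,
    output_grid_step: float = 0.05,
    rtol: float = 1e-7,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate a scenario and return the trajectory on a regular grid.

    The output grid has spacing ``output_grid_step`` (h) and always
    includes ``t0``, ``t_end`` and every event time (lag end, phase
    boundaries, pulses, death-switch crossings).  Raises
    :class:`SimulationError` on integrator failure and ``ValueError`` if
    any stock goes negative beyond integration noise (1e-6 g).
    """
    sc = scenario
    t0, t_end = sc.t0, sc.t_end
    n = int(round((t_end - t0) / output_grid_step))
    grid = np.unique(np.concatenate([t0 + output_grid_step * np.arange(n + 1),
                                     [t_end]]))
    grid = grid[(grid >= t0) & (grid <= t_end)]

    breaks = set(sc.schedule.breakpoints()) | {t0, t_end}
    if t0 < sc.t_lag < t_end:
        breaks.add(sc.t_lag)
    breaks = sorted(b for b in breaks if t0 <= b <= t_end)
    pulses_by_time = {p.time: p for p in sc.schedule.pulses}

    y = np.array(sc.initial_state.to_array() + [0.0])  # + cumulative uptake
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    for t_a, t_b in zip(breaks[:-1], breaks[1:]):
        if t_a in pulses_by_time:
            st = apply_pulse(ReactorState.from_array(y), pulses_by_time[t_a])
            y = np.array(st.to_array() + [y[8]])
        if t_b <= t_a:
            continue
        seg_t, seg_y, y = _integrate_segment(
            y[:9], t_a, t_b, sc, grid, rtol, atol, method
        )
        all_t.append(seg_t)
        all_y.append(seg_y)
    if t_end in pulses_by_time:
        st = apply_pulse(ReactorState.from_array(y), pulses_by_time[t_end])
        y = np.array(st.to_array() + [y[8]])
        all_t.append(np.array([t_end]))
        all_y.append(y[None, :])

    times = np.concatenate(all_t)
    states = np.vstack(all_y)
    # drop duplicated segment endpoints (keep the post-event/post-pulse state)
    keep = np.ones(times.size, dtype=bool)
    keep[:-1] = np.diff(times) > 0
    times, states = times[keep], states[keep]

    low = states[:, :8].min()
    if low < -1e-5:
        raise ValueError(
            f"stock went negative beyond tolerance (min {low:.3e} g); "
            "the scenario is numerically inconsistent"
        )
    np.clip(states[:, :8], 0.0, None, out=states[:, :8])
    return Trajectory(
        times=times,
        states=states[:, :8],
        cumulative_uptake=states[:, 8],
        scenario=sc,
    )


def _living_mass(traj: Trajectory) -> np.ndarray:
    m = traj.column("P") + traj.column("C_M") + traj.column("R")
    if traj.scenario.options.include_dead_in_biomass:
        m = m + traj.column("D")
    return m


def observables(traj: Trajectory) -> Observables:
    """Measurable outputs of a trajectory.

    Biomass is the living dry mass ``P + C_M + R`` (dead cells excluded
    unless the scenario options say otherwise) divided by the
    time-matched volume.  The specific growth rate is the centered finite
    difference of the log of living mass, so it is volume-independent.
    """
    V = traj.column("V")
    mass = _living_mass(traj)
    biomass = mass / V
    with np.errstate(divide="ignore"):
        logm = np.where(mass > 0, np.log(np.maximum(mass, 1e-300)), -np.inf)
    mu = np.gradient(logm, traj.times)
    mu[~np.isfinite(mu)] = 0.0
    return Observables(
        times=traj.times,
        biomass_conc=biomass,
        glucose_conc=traj.column("G") / V,
        acetate_conc=traj.column("A") / V,
        specific_growth_rate=mu,
    )


def max_specific_growth_rate(
    traj: Trajectory, window: tuple[float, float], smooth_points: int = 5
) -> float:
    """Maximum of the smoothed specific-growth-rate series over a window.

    Smoothing is a centered moving average over ``smooth_points`` grid
    points; it leaves a constant-rate (purely exponential) segment exact.
    """
    obs = observables(traj)
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty growth-rate window")
    mask = (obs.times >= lo) & (obs.times <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] contains no trajectory points")
    mu = obs.specific_growth_rate
    k = max(1, smooth_points)
    kernel = np.ones(k) / k
    smoothed = np.convolve(mu, kernel, mode="same")
    return float(smoothed[mask].max())
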