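"""Parameter calibration against sparse concentration time-series.

The objective is the three-output mean-squared error

    SSE = (1/n1) sum_i (B_i - B*_i)^2
        + (1/n2) sum_i (G_i - G*_i)^2
        + (1/n3) sum_i (A_i - A*_i)^2

over biomass, glucose and acetate concentrations (g/L), with model output
linearly interpolated from the dense trajectory grid to the observation
times.  Minimization is a derivative-free Nelder-Mead simplex, run in a
transformed space (log for positive parameters, logit for efficiencies or
explicit bounds) so the simplex can never leave the valid region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import UNIT_INTERVAL_PARAMS, StrainParameters
from .simulate import Scenario, SimulationError, observables, simulate

__all__ = [
    "ObservationSet",
    "CalibrationSpec",
    "CalibrationResult",
    "sse",
    "calibrate",
    "read_observations",
    "write_observations",
]

OUTPUTS = ("biomass", "glucose", "acetate")

#: objective value returned when a candidate parameter set cannot be simulated
FAILURE_PENALTY = 1e12


@dataclass
class ObservationSet:
    """Sparse measurements per output: arrays of (time h, concentration g/L)."""

    times: dict[str, np.ndarray] = field(default_factory=dict)
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for out in list(self.times):
            if out not in OUTPUTS:
                raise ValueError(f"unknown output {out!r}; use one of {OUTPUTS}")
            t = np.asarray(self.times[out], dtype=float)
            v = np.asarray(self.values[out], dtype=float)
            if t.shape != v.shape:
                raise ValueError(f"{out}: times and values differ in length")
            order = np.argsort(t)
            self.times[out] = t[order]
            self.values[out] = v[order]
        if self.n_total == 0:
            raise ValueError("observation set is empty")

    @property
    def n_total(self) -> int:
        return sum(len(t) for t in self.times.values())

    def counts(self) -> dict[str, int]:
        return {out: len(self.times.get(out, ())) for out in OUTPUTS}


def read_observations(path: str | Path) -> ObservationSet:
    """Read observations from CSV with columns time_h, output, value_gL."""
    df = pd.read_csv(path)
    for col in ("time_h", "output", "value_gL"):
        if col not in df.columns:
            raise ValueError(f"observation file {path} missing column {col!r}")
    if df.empty:
        raise ValueError(f"observation file {path} is empty")
    times, values = {}, {}
    for out, grp in df.groupby("output"):
        times[str(out)] = grp["time_h"].to_numpy(float)
        values[str(out)] = grp["value_gL"].to_numpy(float)
    return ObservationSet(times=times, values=values)


def write_observations(obs: ObservationSet, path: str | Path) -> None:
    rows = []
    for out in OUTPUTS:
        for t, v in zip(obs.times.get(out, ()), obs.values.get(out, ())):
            rows.append({"time_h": t, "output": out, "value_gL": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def sse(model_obs, observations: ObservationSet) -> float:
    """Three-term mean-squared error between model and observations.

    ``model_obs`` is an :class:`~microshift.simulate.Observables` series on
    the dense grid; it is linearly interpolated to each observation time.
    An output with no observations contributes 0.
    """
    total = 0.0
    t_model = model_obs.times
    for out in OUTPUTS:
        t_obs = observations.times.get(out)
        if t_obs is None or len(t_obs) == 0:
            continue
        if t_obs.min() < t_model[0] - 1e-9 or t_obs.max() > t_model[-1] + 1e-9:
            raise ValueError(
                f"{out} observation times outside the simulated window "
                f"[{t_model[0]}, {t_model[-1]}]"
            )
        pred = np.interp(t_obs, t_model, model_obs.series(out))
        resid = pred - observations.values[out]
        total += float(np.mean(resid**2))
    return total


@dataclass
class CalibrationSpec:
    """Which parameters to fit, from where, and how hard to try."""

    free_parameters: tuple[str, ...]
    initial_guess: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    max_iterations: int = 2000
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        self.free_parameters = tuple(self.free_parameters)
        if not self.free_parameters:
            raise ValueError("free parameter set must be non-empty")
        valid = {f for f in StrainParameters.__dataclass_fields__}
        for name in self.free_parameters:
            if name not in valid:
                raise ValueError(f"unknown parameter {name!r}")
            if name not in self.initial_guess:
                raise ValueError(f"no initial guess for {name!r}")
            lo, hi = self._bounds_for(name)
            g = self.initial_guess[name]
            if not lo < g < hi:
                raise ValueError(
                    f"initial guess {name}={g} outside bounds ({lo}, {hi})"
                )

    def _bounds_for(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        if name in UNIT_INTERVAL_PARAMS:
            return (1e-9, 1.0)
        return (0.0, math.inf)


# -- transform between physical and unconstrained search space ---------------

def _to_search(x: float, lo: float, hi: float) -> float:
    if math.isinf(hi):
        return math.log(x - lo)
    p = (x - lo) / (hi - lo)
    return math.log(p / (1.0 - p))


def _from_search(z: float, lo: float, hi: float) -> float:
    if math.isinf(hi):
        return lo + math.exp(z)
    return lo + (hi - lo) / (1.0 + math.exp(-z))


@dataclass
class CalibrationResult:
    """Outcome of a calibration run."""

    parameters: dict[str, float]
    sse: float
    initial_sse: float
    iterations: int
    n_evaluations: int
    converged: bool
    residuals: dict[str, np.ndarray]
    message: str = ""


def _as_pairs(scenarios, observations) -> list[tuple[Scenario, ObservationSet]]:
    if isinstance(scenarios, Scenario):
        return [(scenarios, observations)]
    return list(zip(scenarios, observations))


def calibrate(
    scenario,
    observations,
    spec: CalibrationSpec,
    grid_step: float = 0.05,
) -> CalibrationResult:
    """Fit the free parameters by Nelder-Mead minimization of the SSE.

    ``scenario``/``observations`` may be a single pair or two parallel
    lists for joint fitting of several experiments sharing one strain
    parameter set (per-scenario SSE values are summed).  Candidate
    parameter sets that fail to simulate score a large penalty instead of
    aborting the search.  Deterministic: the same guess and options always
    give the same result.
    """
    pairs = _as_pairs(scenario, observations)
    names = spec.free_parameters
    bounds = [spec._bounds_for(n) for n in names]

    def objective_physical(values: dict[str, float]) -> float:
        total = 0.0
        for sc, obs in pairs:
            try:
                params = sc.params.with_(**values)
                traj = simulate(sc_with_params(sc, params), grid_step)
                total += sse(observables(traj), obs)
            except (SimulationError, ValueError, FloatingPointError):
                return FAILURE_PENALTY
        return total

    def sc_with_params(sc: Scenario, params: StrainParameters) -> Scenario:
        return Scenario(
            initial_state=sc.initial_state, schedule=sc.schedule,
            params=params, t0=sc.t0, t_lag=sc.t_lag, options=sc.options,
            name=sc.name,
        )

    n_eval = 0

    def objective(z: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        values = {
            n: _from_search(float(zi), lo, hi)
            for n, zi, (lo, hi) in zip(names, z, bounds)
        }
        return objective_physical(values)

    z0 = np.array([
        _to_search(spec.initial_guess[n], lo, hi)
        for n, (lo, hi) in zip(names, bounds)
    ])
    initial_sse = objective(z0)
    res = minimize(
        objective, z0, method="Nelder-Mead",
        options={
            "maxiter": spec.max_iterations,
            "xatol": spec.tolerance,
            "fatol": spec.tolerance,
        },
    )
    fitted = {
        n: _from_search(float(zi), lo, hi)
        for n, zi, (lo, hi) in zip(names, res.x, bounds)
    }
    final_sse = float(res.fun)
    # Nelder-Mead keeps the best vertex, so this can only improve
    if final_sse > initial_sse:
        fitted = dict(spec.initial_guess)
        final_sse = initial_sse

    residuals: dict[str, np.ndarray] = {}
    sc0, obs0 = pairs[0]
    try:
        traj = simulate(sc_with_params(sc0, sc0.params.with_(**fitted)), grid_step)
        mobs = observables(traj)
        for out in OUTPUTS:
            t_obs = obs0.times.get(out)
            if t_obs is None or len(t_obs) == 0:
                continue
            pred = np.interp(t_obs, mobs.times, mobs.series(out))
            residuals[out] = pred - obs0.values[out]
    except (SimulationError, ValueError):
        pass

    return CalibrationResult(
        parameters=fitted,
        sse=final_sse,
        initial_sse=float(initial_sse),
        iterations=int(res.nit),
        n_evaluations=n_eval,
        converged=bool(res.success),
        residuals=residuals,
        message=str(res.message),
    )
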