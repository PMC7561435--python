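"""Structured configuration: one YAML schema for presets and user scenarios.

A scenario config is a mapping with keys ``initial_state`` (stock masses in
g), ``V0`` (L), ``t0``/``t_end``/``lag`` (h), ``phases`` (list of feeding
phases), ``pulses`` (optional), ``parameters`` (strain constants) and
``options``.  Units are fixed throughout: hours, grams, litres, g/L.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .feeding import FeedingPhase, FeedingSchedule, PulseEvent
from .model import ModelOptions, ReactorState, StrainParameters
from .simulate import Scenario

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "scenario_from_config",
    "scenario_to_config",
]

#: values the source tables never print; echoed in summaries and logs
UNPRINTED_DEFAULTS = ("V0", "P_max", "A_max", "I_max")


class ConfigError(ValueError):
    """A scenario configuration is malformed; the message names the key."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise ConfigError(f"missing required config key: {key!r}")
    return cfg[key]


def scenario_from_config(cfg: dict) -> Scenario:
    """Build a :class:`Scenario` from a parsed configuration mapping."""
    init = _require(cfg, "initial_state")
    v0 = float(_require(cfg, "V0"))
    t0 = float(cfg.get("t0", 0.0))
    t_end = float(_require(cfg, "t_end"))
    lag = float(cfg.get("lag", 0.0) or 0.0)
    try:
        state = ReactorState(
            G=float(init.get("G", 0.0)), P=float(init.get("P", 0.0)),
            A=float(init.get("A", 0.0)), C_M=float(init.get("C_M", 0.0)),
            R=float(init.get("R", 0.0)), I=float(init.get("I", 0.0)),
            D=float(init.get("D", 0.0)), V=v0,
        )
    except AttributeError as e:
        raise ConfigError("initial_state must be a mapping of stock masses") from e

    phases = []
    for i, ph in enumerate(_require(cfg, "phases")):
        try:
            phases.append(FeedingPhase(
                mode=ph["mode"], t_start=float(ph["t_start"]),
                M_F=float(ph.get("M_F", 0.0)), mu=float(ph.get("mu", 0.0)),
                c_F=float(ph.get("c_F", 500.0)), y_R=float(ph.get("y_R", 0.39)),
            ))
        except (KeyError, TypeError, ValueError) as e:
            raise ConfigError(f"phases[{i}]: {e}") from e
    pulses = []
    for i, pu in enumerate(cfg.get("pulses") or []):
        try:
            pulses.append(PulseEvent(
                time=float(pu["time"]), glucose_mass=float(pu["glucose_mass"]),
                volume_added=float(pu.get("volume_added", 0.0)),
                note=str(pu.get("note", "")),
            ))
        except (KeyError, TypeError, ValueError) as e:
            raise ConfigError(f"pulses[{i}]: {e}") from e
    try:
        schedule = FeedingSchedule(
            phases=tuple(phases), V0=v0, t_end=t_end, pulses=tuple(pulses)
        )
    except ValueError as e:
        raise ConfigError(f"phases/schedule: {e}") from e

    raw_params = dict(_require(cfg, "parameters"))
    try:
        params = StrainParameters(**{k: float(v) for k, v in raw_params.items()})
    except TypeError as e:
        raise ConfigError(f"parameters: {e}") from e
    except ValueError as e:
        raise ConfigError(f"parameters: {e}") from e

    opt_cfg = cfg.get("options") or {}
    try:
        options = ModelOptions(**opt_cfg)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"options: {e}") from e

    return Scenario(
        initial_state=state, schedule=schedule, params=params,
        t0=t0, t_lag=t0 + lag, options=options,
        name=str(cfg.get("name", "")),
    )


def scenario_to_config(scenario: Scenario) -> dict:
    """Serialize a scenario back to the configuration schema (round-trips)."""
    st = scenario.initial_state
    cfg: dict = {
        "name": scenario.name,
        "initial_state": {
            k: getattr(st, k) for k in ("G", "P", "A", "C_M", "R", "I", "D")
        },
        "V0": scenario.schedule.V0,
        "t0": scenario.t0,
        "t_end": scenario.t_end,
        "lag": scenario.t_lag - scenario.t0,
        "phases": [
            {"mode": p.mode, "t_start": p.t_start, "M_F": p.M_F, "mu": p.mu,
             "c_F": p.c_F, "y_R": p.y_R}
            for p in scenario.schedule.phases
        ],
        "pulses": [
            {"time": p.time, "glucose_mass": p.glucose_mass,
             "volume_added": p.volume_added, "note": p.note}
            for p in scenario.schedule.pulses
        ],
        "parameters": asdict(scenario.params),
        "options": asdict(scenario.options),
    }
    return cfg
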