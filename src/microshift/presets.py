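"""Shipped experiment presets and the synthetic-observation generator.

Six presets cover the strains and reactor protocols the model was built
around: *E. coli* W3110 (two-phase fed-batch with glucose pulses), three
*E. coli* TG1 cultures (one high-cell-density), two recombinant TG1 runs
and one *B. subtilis* fed-batch.  Every numeric field traces to a printed
table cell except the initial volume and the three ceiling
concentrations, which are documented defaults, and the W3110 pulse
times/masses, which are placeholders.

The observation generator emulates how such cultures are actually
sampled: a handful of time points per output (typically 5-20), each
measurement carrying multiplicative Gaussian error.  It exists so the
calibration machinery can be exercised end-to-end without any external
data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .calibrate import OUTPUTS, ObservationSet
from .config import scenario_from_config
from .simulate import Scenario, Trajectory, observables

__all__ = [
    "PRESET_NAMES",
    "Preset",
    "NoiseModel",
    "load_preset",
    "preset_config",
    "generate_observations",
    "default_sampling_times",
]

PRESET_NAMES = (
    "ecoli_W3110",
    "ecoli_TG1_riesenberg",
    "ecoli_TG1_gen",
    "ecoli_TG1_rec_fiedler",
    "ecoli_TG1_rec_seeger",
    "bsubtilis_huang",
)


@dataclass(frozen=True)
class Preset:
    name: str
    scenario: Scenario
    config: dict
    description: str = ""
    provenance: str = ""
    defaults_used: tuple[str, ...] = ()


def preset_config(name: str) -> dict:
    """Raw configuration mapping of a shipped preset."""
    if name not in PRESET_NAMES:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    text = resources.files("microshift.data").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def load_preset(name: str) -> Preset:
    """Load a shipped preset into a ready-to-simulate scenario."""
    cfg = preset_config(name)
    return Preset(
        name=name,
        scenario=scenario_from_config(cfg),
        config=cfg,
        description=str(cfg.get("description", "")).strip(),
        provenance=str(cfg.get("provenance", "")).strip(),
        defaults_used=tuple(cfg.get("defaults_used", ())),
    )


@dataclass
class NoiseModel:
    """Sparse-sampling measurement model for synthetic observations.

    Each output is sampled at ``sampling_times[output]`` and perturbed
    multiplicatively: ``value = truth * (1 + eps)`` with
    ``eps ~ N(0, relative_sd)``, independent per point; negative draws are
    clamped to zero (concentrations cannot be negative).  The default
    relative standard deviation of 5 % is typical of dry-weight, glucose
    and HPLC acetate assays.
    """

    relative_sd: float | dict[str, float] = 0.05
    sampling_times: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def sd_for(self, output: str) -> float:
        if isinstance(self.relative_sd, dict):
            return float(self.relative_sd.get(output, 0.0))
        return float(self.relative_sd)

    def __post_init__(self) -> None:
        sds = (
            self.relative_sd.values()
            if isinstance(self.relative_sd, dict)
            else [self.relative_sd]
        )
        if any(sd < 0 for sd in sds):
            raise ValueError("relative_sd must be >= 0")


def default_sampling_times(
    scenario: Scenario, n_per_output: int = 15
) -> dict[str, np.ndarray]:
    """Evenly spaced sampling times over the scenario window for each output."""
    t = np.linspace(scenario.t0, scenario.t_end, n_per_output + 2)[1:-1]
    return {out: t.copy() for out in OUTPUTS}


def generate_observations(trajectory: Trajectory, noise: NoiseModel) -> ObservationSet:
    """Sample a simulated trajectory into a noisy sparse observation set.

    Reproducible: the same trajectory, times and seed always produce the
    same observations.
    """
    rng = np.random.default_rng(noise.seed)
    obs = observables(trajectory)
    times, values = {}, {}
    for out in OUTPUTS:
        t = noise.sampling_times.get(out)
        if t is None or len(t) == 0:
            continue
        t = np.asarray(t, dtype=float)
        if t.min() < obs.times[0] - 1e-9 or t.max() > obs.times[-1] + 1e-9:
            raise ValueError(f"{out} sampling times outside the trajectory window")
        truth = np.interp(t, obs.times, obs.series(out))
        eps = rng.normal(0.0, noise.sd_for(out), size=t.shape)
        values[out] = np.maximum(truth * (1.0 + eps), 0.0)
        times[out] = t
    return ObservationSet(times=times, values=values)
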