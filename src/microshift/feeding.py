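"""Feeding regimes and medium-volume dynamics for batch and fed-batch operation.

A schedule is an ordered list of phases.  A *batch* phase feeds nothing.
An *exponential* phase feeds at ``F(t) = F0 exp(mu (t - t_start))`` so that
a population growing at the imposed specific feeding rate ``mu`` stays
glucose-limited; a *constant* phase feeds at ``F0`` throughout.  The
initial volumetric rate of a fed phase is computed from the cell mass at
the moment feeding starts::

    F0 = M_F * mu / (c_F * y_R)

where ``c_F`` is the glucose concentration of the feed (g/L) and ``y_R``
the maximum biomass yield on glucose.  Discrete glucose pulses can be
superimposed on any phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import ReactorState

__all__ = [
    "FeedingPhase",
    "PulseEvent",
    "FeedingSchedule",
    "initial_feed_rate",
    "feed_rate",
    "volume_at",
    "apply_pulse",
]

MODES = ("batch", "exponential", "constant")


def initial_feed_rate(M_F: float, mu: float, c_F: float, y_R: float) -> float:
    """Initial volumetric feed rate ``F0 = M_F mu / (c_F y_R)`` in L/h."""
    if c_F <= 0 or y_R <= 0:
        raise ValueError(
            f"feed concentration c_F={c_F} and yield y_R={y_R} must be > 0"
        )
    if M_F < 0 or mu < 0:
        raise ValueError("M_F and mu must be non-negative")
    return M_F * mu / (c_F * y_R)


@dataclass(frozen=True)
class FeedingPhase:
    """One operating phase of the reactor.

    ``M_F`` is the cell mass (g) at the start of the phase, ``mu`` the
    specific feeding rate (1/h), ``c_F`` the feed glucose concentration
    (g/L) and ``y_R`` the maximum biomass yield on glucose.  Batch phases
    ignore the feed fields.
    """

    mode: str
    t_start: float
    M_F: float = 0.0
    mu: float = 0.0
    c_F: float = 500.0
    y_R: float = 0.39

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown phase mode {self.mode!r}; use one of {MODES}")
        if self.mode != "batch":
            if self.c_F <= 0:
                raise ValueError("c_F must be > 0 for a fed phase")
            if not 0.0 < self.y_R <= 1.0:
                raise ValueError("y_R must lie in (0, 1]")
            if self.mu < 0:
                raise ValueError("mu must be >= 0")

    @property
    def F0(self) -> float:
        """Volumetric feed rate at the start of the phase (L/h)."""
        if self.mode == "batch":
            return 0.0
        return initial_feed_rate(self.M_F, self.mu, self.c_F, self.y_R)

    def rate_at(self, t: float) -> float:
        """Volumetric feed rate (L/h) at absolute time ``t`` within the phase."""
        if self.mode == "batch":
            return 0.0
        if self.mode == "exponential":
            return self.F0 * math.exp(self.mu * (t - self.t_start))
        return self.F0

    def fed_volume(self, t_from: float, t_to: float) -> float:
        """Closed-form volume (L) fed over ``[t_from, t_to]`` within the phase."""
        if self.mode == "batch" or t_to <= t_from:
            return 0.0
        if self.mode == "exponential":
            if self.mu == 0.0:
                return self.F0 * (t_to - t_from)
            return (self.F0 / self.mu) * (
                math.exp(self.mu * (t_to - self.t_start))
                - math.exp(self.mu * (t_from - self.t_start))
            )
        return self.F0 * (t_to - t_from)


@dataclass(frozen=True)
class PulseEvent:
    """Instantaneous addition of glucose (and optionally volume)."""

    time: float
    glucose_mass: float
    volume_added: float = 0.0
    note: str = ""

    def __post_init__(self) -> None:
        if self.glucose_mass < 0 or self.volume_added < 0:
            raise ValueError("pulse glucose mass and volume must be >= 0")


@dataclass(frozen=True)
class FeedingSchedule:
    """Ordered feeding phases plus pulses, initial volume and end time."""

    phases: tuple[FeedingPhase, ...]
    V0: float = 1.0
    t_end: float = 0.0
    pulses: tuple[PulseEvent, ...] = ()

    def __post_init__(self) -> None:
        phases = tuple(self.phases)
        pulses = tuple(sorted(self.pulses, key=lambda p: p.time))
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "pulses", pulses)
        if not phases:
            raise ValueError("schedule needs at least one phase")
        starts = [p.t_start for p in phases]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("phase start times must be non-decreasing")
        if self.V0 <= 0:
            raise ValueError("initial volume V0 must be > 0")
        if self.t_end <= phases[0].t_start:
            raise ValueError("t_end must lie after the first phase start")
        for p in pulses:
            if not phases[0].t_start <= p.time <= self.t_end:
                raise ValueError(
                    f"pulse at t={p.time} outside window "
                    f"[{phases[0].t_start}, {self.t_end}]"
                )

    @property
    def t_start(self) -> float:
        return self.phases[0].t_start

    def phase_at(self, t: float) -> FeedingPhase:
        active = self.phases[0]
        for p in self.phases:
            if p.t_start <= t:
                active = p
            else:
                break
        return active

    def breakpoints(self) -> list[float]:
        """Times where the feed is discontinuous (phase starts and pulses)."""
        pts = {p.t_start for p in self.phases} | {p.time for p in self.pulses}
        return sorted(t for t in pts if self.t_start <= t <= self.t_end)


def feed_rate(t: float, schedule: FeedingSchedule) -> tuple[float, float]:
    """Volumetric (L/h) and glucose mass (g/h) feed rates at time ``t``."""
    if not schedule.t_start <= t <= schedule.t_end:
        raise ValueError(
            f"t={t} outside schedule window [{schedule.t_start}, {schedule.t_end}]"
        )
    phase = schedule.phase_at(t)
    v = phase.rate_at(t)
    return v, phase.c_F * v if phase.mode != "batch" else 0.0


def volume_at(t: float, schedule: FeedingSchedule) -> float:
    """Medium volume at ``t``: ``V0`` plus cumulative feed plus pulse volumes.

    Uses the exact integral of the feed rate per phase, so the volume is
    continuous everywhere except at pulses that add volume.
    """
    if not schedule.t_start <= t <= schedule.t_end:
        raise ValueError(
            f"t={t} outside schedule window [{schedule.t_start}, {schedule.t_end}]"
        )
    v = schedule.V0
    phases = schedule.phases
    for i, phase in enumerate(phases):
        if phase.t_start >= t:
            break
        stop = phases[i + 1].t_start if i + 1 < len(phases) else schedule.t_end
        v += phase.fed_volume(phase.t_start, min(t, stop))
    v += sum(p.volume_added for p in schedule.pulses if p.time <= t)
    return v


def apply_pulse(state: ReactorState, pulse: PulseEvent) -> ReactorState:
    """Return the state right after an instantaneous glucose pulse."""
    return ReactorState(
        G=state.G + pulse.glucose_mass,
        P=state.P, A=state.A, C_M=state.C_M, R=state.R, I=state.I, D=state.D,
        V=state.V + pulse.volume_added,
    )
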