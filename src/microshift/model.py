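"""Core mass-balance model of microbial growth with the respiration/fermentation shift.

The model tracks seven stocks (all in grams) in a stirred bioreactor of
volume ``V`` (litres):

``G``
    glucose dissolved in the medium;
``P``
    pooled glycolytic intermediates (glucose-6-phosphate through pyruvate),
    the regulatory hub of the model;
``A``
    acetate excreted by fermentation;
``C_M``
    cellular components built by respiration or fermentation;
``R``
    reserve compounds;
``I``
    growth-associated inhibitory by-products;
``D``
    dead cell mass.

The intracellular concentration of glycolytic intermediates ``[P]`` drives
every regulatory switch: a logistic "glucose effect" ``ge`` represses
respiration as ``[P]`` rises, its complement ``mo = 1 - ge`` is the overflow
fraction routed to fermentation, reserve accumulation scales with ``mo``,
and mortality switches on when ``[P]`` exceeds a threshold ``tau``.
Extracellular acetate and inhibitors feed back linearly on the growth
fluxes.  All fluxes are one-way, so every feedback multiplier is clamped to
``[0, 1]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = [
    "ReactorState",
    "StrainParameters",
    "ModelOptions",
    "DerivedQuantities",
    "ProcessRates",
    "STATE_FIELDS",
    "glucose_effect",
    "acetate_allocation",
    "feedback_factors",
    "derive",
    "process_rates",
    "rhs",
]

#: order of the physical state vector handed to the integrator
STATE_FIELDS = ("G", "P", "A", "C_M", "R", "I", "D", "V")

# exp() overflows a little past 709; beyond this the logistic is 0 anyway
_EXP_MAX = 700.0


@dataclass
class ReactorState:
    """Masses of the seven stocks (g) and the medium volume ``V`` (L)."""

    G: float
    P: float
    A: float
    C_M: float
    R: float
    I: float
    D: float
    V: float

    def to_array(self) -> list[float]:
        return [getattr(self, f) for f in STATE_FIELDS]

    @classmethod
    def from_array(cls, y) -> "ReactorState":
        return cls(*(float(v) for v in y[:8]))

    def validate(self) -> None:
        for f in STATE_FIELDS:
            v = getattr(self, f)
            if not math.isfinite(v):
                raise ValueError(f"non-finite reactor state component {f}={v}")
        if self.V <= 0:
            raise ValueError(f"medium volume must be positive, got V={self.V}")


# names of efficiency-like parameters constrained to (0, 1]
UNIT_INTERVAL_PARAMS = frozenset(
    {"etaG", "etaRP", "etaFA", "etaFP", "etaRA", "etaA", "r_max"}
)


@dataclass(frozen=True)
class StrainParameters:
    """Kinetic and regulatory constants of one microbial strain.

    Rates ``v*`` are maximum specific rates (1/h), ``k*`` are Monod
    saturation constants (g/L) and ``eta*`` are mass-conversion
    efficiencies (dimensionless, in ``(0, 1]``).  ``P_max``, ``A_max`` and
    ``I_max`` are the ceiling concentrations (g/L) that normalise the
    regulatory feedbacks; they are scenario-level choices rather than
    tabulated strain constants and every preset records the values used.
    """

    vG: float      #: maximum glucose uptake rate (1/h)
    kG: float      #: uptake saturation constant (g/L)
    etaG: float    #: uptake efficiency P/G
    vRP: float     #: maximum respiration rate on glycolytic intermediates (1/h)
    kRP: float     #: its saturation constant (g/L)
    etaRP: float   #: respiration efficiency C_M/P
    vF: float      #: maximum fermentation rate (1/h)
    kF: float      #: fermentation saturation constant (g/L)
    etaFA: float   #: fermentation efficiency A/P
    etaFP: float   #: fermentation efficiency C_M/P
    vRA: float     #: maximum acetate respiration rate (1/h)
    kRA: float     #: its saturation constant (g/L)
    etaRA: float   #: respiration efficiency C_M/A
    vA: float      #: maximum reserve accumulation rate (1/h)
    kA: float      #: accumulation saturation constant (g/L)
    etaA: float    #: accumulation efficiency R/P
    r_max: float   #: maximum reserves / active-mass ratio
    delta: float   #: death rate once the death switch is on (1/h)
    tau: float     #: death threshold on intracellular [P] (g/L)
    rho: float     #: secretion rate of inhibitory by-products (1/h)
    sigma_I: float  #: sensitivity to the inhibitor feedback
    sigma_A: float  #: sensitivity to the acetate feedback
    c: float       #: cell volume per dry weight (L/g)
    a1: float      #: respiration/fermentation switch shape
    b1: float      #: respiration/fermentation switch steepness (L/g)
    a2: float      #: mixed-fermentation switch shape
    b2: float      #: mixed-fermentation switch steepness (L/g)
    P_max: float = 3.0   #: ceiling intracellular [P] (g/L); unprinted default
    A_max: float = 20.0  #: ceiling [A] (g/L); unprinted default
    I_max: float = 30.0  #: ceiling [I] (g/L); unprinted default

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v}")
            if f.name in UNIT_INTERVAL_PARAMS:
                if not 0.0 < v <= 1.0:
                    raise ValueError(
                        f"efficiency {f.name} must lie in (0, 1], got {v}"
                    )
            elif f.name in ("delta", "tau", "rho", "sigma_I", "sigma_A"):
                if v < 0:
                    raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")
        if not 0.0 < self.r_max < 1.0:
            raise ValueError(f"r_max must lie in (0, 1), got {self.r_max}")

    def with_(self, **updates) -> "StrainParameters":
        """Return a copy with the named parameters replaced."""
        return replace(self, **updates)

    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self))


@dataclass(frozen=True)
class ModelOptions:
    """Switches for the points where the published equations are ambiguous.

    ``ne_feedback`` selects which negative feedback multiplies glucose
    uptake (the analogue of the ethanol feedback in the precursor yeast
    model): ``"acetate"`` (default), ``"inhibitor"`` or ``"none"``.
    ``include_dead_in_biomass`` adds the dead-cell stock to the biomass
    observable.  ``smooth_death_switch`` replaces the hard death threshold
    with a steep logistic of width ``death_smoothing_width`` (g/L), useful
    when the exact event handling is not wanted.
    """

    ne_feedback: str = "acetate"
    include_dead_in_biomass: bool = False
    smooth_death_switch: bool = False
    death_smoothing_width: float = 0.01

    def __post_init__(self) -> None:
        if self.ne_feedback not in ("acetate", "inhibitor", "none"):
            raise ValueError(
                "ne_feedback must be 'acetate', 'inhibitor' or 'none', "
                f"got {self.ne_feedback!r}"
            )


DEFAULT_OPTIONS = ModelOptions()


@dataclass
class DerivedQuantities:
    """Concentrations and regulatory factors evaluated at one state."""

    Gconc: float   #: [G] = G/V (g/L)
    Aconc: float   #: [A] = A/V (g/L)
    Iconc: float   #: [I] = I/V (g/L)
    B: float       #: active metabolite mass P + C_M (g)
    Pconc: float   #: [P] = P/((B+R) c) (g/L)
    Rmax_abs: float  #: (B+R) r_max, reserve ceiling (g)
    nA: float      #: acetate negative feedback sigma_A [A]/[A]max
    nI: float      #: inhibitor negative feedback sigma_I [I]/[I]max
    ge: float      #: glucose effect (respiration share)
    mo: float      #: metabolic overflow, 1 - ge (fermentation share)
    fa: float      #: fraction of fermentative flux yielding acetate
    lag: float     #: 0 before the lag ends, 1 after
    d: float       #: death switch, 1 iff [P] > tau


@dataclass
class ProcessRates:
    """Mass fluxes (g/h) of the model processes at one instant."""

    uptake: float
    respiration_p: float
    fermentation: float
    respiration_a: float
    accumulation: float
    secretion: float
    death_p: float
    death_r: float
    death_cm: float


def _logistic_decay(x: float, a: float, b: float) -> float:
    # 1 / (1 + a e^{bx}) with overflow guard returning the asymptote
    z = b * x
    if z > _EXP_MAX:
        return 0.0
    return 1.0 / (1.0 + a * math.exp(z))


def glucose_effect(Pconc: float, a1: float, b1: float) -> float:
    """Glucose effect ``ge = 1/(1 + a1 exp(b1 [P]))``.

    Strictly decreasing in ``[P]``: respiration is progressively repressed
    as glycolytic intermediates accumulate.
    """
    return _logistic_decay(Pconc, a1, b1)


def acetate_allocation(Aconc: float, a2: float, b2: float) -> float:
    """Fraction ``fa = 1/(1 + a2 exp(b2 [A]))`` of fermentation going to acetate.

    Decreasing in ``[A]``: as acetate accumulates, mixed fermentation
    diverts a growing share of the flux to secondary by-products.
    """
    return _logistic_decay(Aconc, a2, b2)


def feedback_factors(
    Aconc: float, Iconc: float, params: StrainParameters
) -> tuple[float, float, bool, bool]:
    """Linear negative feedbacks ``nA``, ``nI`` and their clamp flags.

    Returns ``(nA, nI, clamped_A, clamped_I)``.  The raw factors are
    ``sigma_A [A]/[A]max`` and ``sigma_I [I]/[I]max``; the downstream
    multipliers ``(1 - n)`` are clamped to ``[0, 1]``, and the flags report
    whether the clamp was active (feedback saturated).
    """
    nA = params.sigma_A * Aconc / params.A_max
    nI = params.sigma_I * Iconc / params.I_max
    return nA, nI, nA > 1.0, nI > 1.0


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def derive(
    state: ReactorState,
    params: StrainParameters,
    t: float,
    t_lag: float = 0.0,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> DerivedQuantities:
    """Evaluate every concentration and regulatory factor at one state.

    ``[I]`` is computed as ``I/V`` in parallel with ``[G]`` and ``[A]``.
    With no cells (``B + R = 0``) the intracellular concentration ``[P]``
    is defined as 0.
    """
    state.validate()
    V = state.V
    Gconc = state.G / V
    Aconc = state.A / V
    Iconc = state.I / V
    B = state.P + state.C_M
    BR = B + state.R
    Pconc = state.P / (BR * params.c) if BR > 0.0 else 0.0
    ge = glucose_effect(Pconc, params.a1, params.b1)
    mo = 1.0 - ge
    fa = acetate_allocation(Aconc, params.a2, params.b2)
    nA, nI, _, _ = feedback_factors(Aconc, Iconc, params)
    if options.smooth_death_switch:
        d = 1.0 / (1.0 + math.exp(
            _clamp(-(Pconc - params.tau) / options.death_smoothing_width,
                   -_EXP_MAX, _EXP_MAX)))
    else:
        d = 1.0 if Pconc > params.tau else 0.0
    lag = 1.0 if t >= t_lag else 0.0
    return DerivedQuantities(
        Gconc=Gconc, Aconc=Aconc, Iconc=Iconc, B=B, Pconc=Pconc,
        Rmax_abs=BR * params.r_max, nA=nA, nI=nI, ge=ge, mo=mo, fa=fa,
        lag=lag, d=d,
    )


def _clamp(x: float, lo: float, hi: float) -> float:
    return lo if x < lo else (hi if x > hi else x)


def _monod(conc: float, k: float) -> float:
    return conc / (k + conc) if conc > 0.0 else 0.0


def process_rates(
    dq: DerivedQuantities,
    state: ReactorState,
    params: StrainParameters,
    death_active: float | None = None,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> ProcessRates:
    """Mass fluxes of every model process given the derived quantities.

    ``death_active`` overrides the death switch in ``dq``; the integrator
    uses this to hold the switch fixed between threshold crossings located
    by root-finding.  All rates are non-negative by construction: the
    saturation terms vanish on empty stocks and every feedback multiplier
    is clamped to ``[0, 1]``.
    """
    mA = _clamp01(1.0 - dq.nA)
    mI = _clamp01(1.0 - dq.nI)
    if options.ne_feedback == "acetate":
        mE = mA
    elif options.ne_feedback == "inhibitor":
        mE = mI
    else:
        mE = 1.0
    B = dq.B

    uptake = (
        params.vG * _monod(dq.Gconc, params.kG) * B
        * _clamp01(1.0 - dq.Pconc / params.P_max) * mE * dq.lag
    )
    resp_p = params.vRP * _monod(dq.Pconc, params.kRP) * B * mA * mI * dq.ge
    ferm = params.vF * _monod(dq.Pconc, params.kF) * B * mA * mI * dq.mo
    resp_a = params.vRA * _monod(dq.Aconc, params.kRA) * B * mA * mI * dq.ge
    room = _clamp01(1.0 - state.R / dq.Rmax_abs) if dq.Rmax_abs > 0.0 else 0.0
    accum = params.vA * _monod(dq.Pconc, params.kA) * B * room * dq.mo
    secretion = params.rho * (
        params.etaRP * resp_p + params.etaRA * resp_a + params.etaFP * ferm
    )
    d = dq.d if death_active is None else death_active
    return ProcessRates(
        uptake=uptake,
        respiration_p=resp_p,
        fermentation=ferm,
        respiration_a=resp_a,
        accumulation=accum,
        secretion=secretion,
        death_p=d * params.delta * state.P,
        death_r=d * params.delta * state.R,
        death_cm=d * params.delta * state.C_M,
    )


def rhs(
    t: float,
    state: ReactorState,
    params: StrainParameters,
    feed_volumetric: float,
    feed_glucose: float,
    t_lag: float = 0.0,
    death_active: float | None = None,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> tuple[list[float], ProcessRates]:
    """Right-hand side of the mass-balance system.

    ``feed_volumetric`` (L/h) and ``feed_glucose`` (g/h) are the feeding
    terms supplied by the reactor schedule; glucose is the only fed
    substrate.  Returns the 8 derivatives in :data:`STATE_FIELDS` order
    together with the process rates used to build them.
    """
    dq = derive(state, params, t, t_lag, options)
    r = process_rates(dq, state, params, death_active, options)
    dG = feed_glucose - r.uptake
    dP = (
        params.etaG * r.uptake
        - r.respiration_p - r.fermentation - r.accumulation - r.death_p
    )
    dA = params.etaFA * r.fermentation * dq.fa - r.respiration_a
    dCM = (
        params.etaRP * r.respiration_p
        + params.etaRA * r.respiration_a
        + params.etaFP * r.fermentation
        - r.secretion - r.death_cm
    )
    dR = params.etaA * r.accumulation - r.death_r
    dI = r.secretion
    dD = r.death_p + r.death_cm + r.death_r
    dV = feed_volumetric
    deriv = [dG, dP, dA, dCM, dR, dI, dD, dV]
    if not all(math.isfinite(v) for v in deriv):
        raise FloatingPointError(
            f"non-finite derivative at t={t}: {deriv}"
        )
    return deriv, r
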