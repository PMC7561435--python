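# Methods

## Model and assumptions

`microshift` is a macro-kinetic, process-based (System Dynamics) model of
a glucose-fed microbial culture.  It deliberately ignores molecular
detail: the working assumption is that the pooled glycolytic
intermediates ($P$, glucose-6-phosphate through pyruvate) are the single
regulatory hub of catabolism.  High intracellular $[P]$ simultaneously
(i) activates aerobic fermentation (overflow), (ii) represses respiration
(the "glucose effect"), (iii) drives reserve accumulation and (iv) above
a threshold $\tau$ switches on mortality.  Oxygen, pH and temperature are
not modelled; aerobic conditions are implicit.  Acetate can be
re-assimilated respiratorily whenever glucose is limiting, with no
secondary acetate-consumption pathways.  Fermentation is "mixed": only a
fraction $f_a([A])$ of the fermentative outflow appears as acetate, the
rest stands for unmeasured by-products (lactate, propionate) whose
accumulation is accounted for in the flux balance but not integrated as
a stock.  Growth-associated inhibitors $I$ are produced proportionally to
the anabolic fluxes and never degraded, which is what ends growth in
prolonged high-cell-density runs.

All seven stocks are masses (g); concentrations divide by the medium
volume $V(t)$, and the intracellular $[P]$ divides by the cell volume
$(B+R)\,c$ where $c$ (L/g) converts dry mass to cell volume.  The
biomass observable is the living dry mass $(P + C_M + R)/V$; dead cells
are excluded by default (`ModelOptions.include_dead_in_biomass` flips
this).  The measured-mass anchors of the reproduced protocols (cell mass
at feeding start) match this definition better than $C_M$ alone.

### Resolved ambiguities

Decisions taken where the published equation set is ambiguous, all
exposed as code rather than buried:

- the uptake feedback symbol is interpreted as the acetate feedback
  $n_A$ (the analogue of the ethanol feedback in the precursor yeast
  model); `ModelOptions.ne_feedback` switches to the inhibitor feedback
  or to none for structure checks;
- $[I]$ is computed as $I/V$, parallel to $[G]$ and $[A]$;
- feedback multipliers $(1-n_A)$, $(1-n_I)$, $(1-[P]/[P]_{max})$,
  $(1-R/R_{max})$ are clamped to $[0,1]$: with $\sigma_A > 1$ they would
  otherwise turn one-way fluxes negative;
- $[P]$ is defined as 0 when no cells are present;
- the logistic switches return their asymptotic limit instead of
  overflowing `exp`;
- the reactor volume uses the exact integral of the feed rate
  ($V_0 + (F_0/\mu)(e^{\mu\Delta t}-1)$ for an exponential phase), which
  is continuous at the feeding start — the closed form printed with the
  original model jumps there and is treated as an erratum.

## Parameters

Strain constants (`StrainParameters`) are the published calibrated
values per strain: maximum specific rates $v$ (1/h), saturation
constants $k$ (g/L), conversion efficiencies $\eta \in (0,1]$, reserve
ratio $r_{max}$, death rate $\delta$ and threshold $\tau$, secretion
rate $\rho$, feedback sensitivities $\sigma_A, \sigma_I$, the
dry-mass-to-volume factor $c$, and the two logistic switch shapes
$(a_1,b_1)$, $(a_2,b_2)$.

Three ceilings are required by the equations but have no published
values.  The package defaults are $[P]_{max} = 3$ g/L,
$[A]_{max} = 20$ g/L, $[I]_{max} = 30$ g/L, chosen so that the
feedbacks are weak early in a culture and material only late in
high-density runs ($[P]$ stays at ~0.5 g/L in a W3110 batch, i.e. the
uptake penalty is ~18 %; inhibition becomes decisive only past
~100 g/L cell density).  The initial medium volume $V_0$ is likewise
unpublished and defaults to 1 L, making initial masses numerically equal
to initial concentrations.  Every preset records these as
`defaults_used` and the CLI echoes them in each summary.  The headline
quantities of the reproduced runs (peak acetate, $\mu_{max}$, final
densities) inherit an uncertainty of a few tens of percent from these
four numbers; they are reported as computed, not adjusted.

One published setup value is overridden: the *B. subtilis* feeding rate
is 0.12 1/h (stated twice in the run description and consistent with the
reported final density of ~17 g/L), not the 0.24 printed in the setup
table, which appears to be a doubling misprint.  The W3110 preset keeps
its table values (feeding from 11.5 h at 0.3 then 0.19 1/h) even though
the run description quotes 13 h and 0.22/0.11 1/h; the discrepancy is
inherited from the source and is the main reason the simulated
exponential-window acetate peak (0.82 g/L) overshoots the described
0.3 g/L — with the described protocol it is 0.57 g/L.  The three W3110
glucose pulses have no published times or masses; the preset carries
placeholders (19, 23, 27 h, 1 g) that are flagged unverifiable.

## Numerics

The system is integrated with SciPy's `solve_ivp` (LSODA by default;
any stiff-capable method can be passed), `rtol = 1e-7`,
`atol = 1e-10`.  Integration is segmented at every known discontinuity —
lag end, feeding-phase starts, pulses — and the discontinuous death
switch is handled exactly: within a segment the switch is frozen and a
terminal event locates the crossing of $[P] - \tau$, where integration
restarts with the switch flipped (a steep-logistic smoothing is
available behind `ModelOptions.smooth_death_switch`, default off).  More
than 200 crossings in one segment abort with a chattering diagnostic.
Uptake is additionally integrated as a quadrature state so the glucose
ledger (initial + fed = residual + consumed) closes to solver accuracy
(< 1e-6 relative on every preset) independent of the output grid.  The
default output grid is 0.05 h.  Tiny negative excursions of a stock are
treated as integration noise (rates see them as zero, outputs clamp them
to zero); anything below −1e-5 g raises.  Lag is implemented by starting
uptake at $t_L$ while integrating from $t_0$, so pre-lag turnover of the
initial stocks is captured.

The specific growth rate is the centred finite difference of
$\ln(P+C_M+R)$ — mass-based, hence volume-independent;
`max_specific_growth_rate` smooths it with a 5-point moving average,
which leaves constant-rate segments exact.  Note that the first ~2 h of
any run show an elevated rate while the (arbitrarily small) initial $P$
pool fills toward its quasi-steady share of biomass; the quasi-steady
batch rate of the W3110 preset is 0.36–0.37 1/h versus a literal maximum
of 0.47 1/h.

Calibration minimises the unweighted three-output mean-squared error
(biomass, glucose, acetate, each averaged over its own sample count)
with Nelder–Mead, the model linearly interpolated to the observation
times.  The search runs in a transformed space — log for positive
parameters, logit for efficiencies or explicit bounds — so the simplex
cannot leave the valid region; simplex and function tolerances are both
1e-8 with at most 2000 iterations, and a candidate that fails to
simulate scores 1e12 instead of aborting.  Joint fitting of several
experiments sharing one parameter set sums per-scenario SSE.  Because
the SSE is unweighted, outputs with large absolute values dominate: in a
high-density run the biomass term is ~3 orders of magnitude above the
acetate term, so parameters expressed mainly through acetate (e.g. the
fermentation rate $v_F$) are weakly identified from noisy data.

The sensitivity index for a ±5 % one-at-a-time perturbation is the mean
over the dense grid of the summed squared deviations of the three
outputs, each normalised by its baseline range; a constant baseline
output is dropped with a warning, and a perturbation that leaves the
admissible parameter space (e.g. +5 % on an efficiency of 0.99) is
recorded as a failure rather than simulated.

## Synthetic observations

`generate_observations` emulates how such cultures are sampled: 5–20
time points per output, each measured with independent multiplicative
Gaussian error (default relative SD 5 %, typical of dry-weight, enzymatic
glucose and HPLC acetate assays), negative draws clamped to zero,
seeded and reproducible.  It does not emulate autocorrelated assay
drift, detection limits, sampling-volume loss or irregular sampling
designs — so calibration tests passing on these data show that the
pipeline recovers parameters under idealised noise, not that every
parameter is identifiable from a given real data set.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the presets at their full
published durations (22–35 h) on the default 0.05 h grid; parameter
recovery uses 15 samples per output on one TG1 scenario; the sensitivity
rankings use a 0.1 h grid.  These sizes keep the whole suite within a
few minutes on one CPU while leaving all reported quantities unchanged
at finer grids (grid-refinement agreement is itself tested).

## Known limitations

- No oxygen/kLa, pH or temperature dynamics; no recombinant-product
  induction kinetics (the reproduced recombinant runs showed none).
- Secondary fermentation by-products are a flux, not a stock; secondary
  acetate-consumption pathways are absent.
- The unpublished ceilings and $V_0$ make absolute concentrations of the
  preset runs uncertain at the tens-of-percent level; trends and
  qualitative shift behaviour are robust to them.
- Nelder–Mead is local; bad starting guesses find local minima, and no
  uncertainty quantification is provided.
- Glucose transporters are constant within a strain; transporter
  regulation under varying glucose is outside the model.
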